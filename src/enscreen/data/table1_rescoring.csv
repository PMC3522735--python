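compound,mmpbsa_rank,autodock_rank,mmpbsa_be_kcal_mol,logp
1,1,185,-11.3,4.7
2,2,62,-11.0,3.4
3,5,139,-10.7,3.1
4,9,112,-9.9,4.4
5,4,63,-9.6,3.7
6,11,128,-9.3,3.3
7,13,59,-8.9,3.4
8,23,181,-8.2,2.7
9,29,138,-7.7,4.3
10,34,54,-7.4,2.6
11,37,131,-7.2,3.1
12,45,104,-7.0,2.5
13,46,44,-6.9,-0.1
14,47,129,-6.8,3.4
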