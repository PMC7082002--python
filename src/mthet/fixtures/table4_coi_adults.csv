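specimen,role,sex,tissue,mother_id,population,position,base1,base2,pct1,pct2
MbraAG-2TM-muscle,adult,male,muscle,,GolfoArtabro,240,T,C,15.3,84.7
MbraAG-2TM-muscle,adult,male,muscle,,GolfoArtabro,264,T,C,0,100
MbraAG-2TM-muscle,adult,male,muscle,,GolfoArtabro,303,T,C,20.2,79.8
MbraAG-2TM-muscle,adult,male,muscle,,GolfoArtabro,375,T,C,100,0
MbraAG-8TM-muscle,adult,male,muscle,,GolfoArtabro,240,T,C,100,0
MbraAG-8TM-muscle,adult,male,muscle,,GolfoArtabro,264,T,C,0,100
MbraAG-8TM-muscle,adult,male,muscle,,GolfoArtabro,303,T,C,100,0
MbraAG-8TM-muscle,adult,male,muscle,,GolfoArtabro,375,T,C,80.9,19.1
MbraAG-10H-muscle,adult,female,muscle,,GolfoArtabro,240,T,C,26.4,73.6
MbraAG-10H-muscle,adult,female,muscle,,GolfoArtabro,264,T,C,0,100
MbraAG-10H-muscle,adult,female,muscle,,GolfoArtabro,303,T,C,31.0,69.0
MbraAG-10H-muscle,adult,female,muscle,,GolfoArtabro,375,T,C,100,0
MbraAG-29TM-muscle,adult,male,muscle,,GolfoArtabro,240,T,C,0,100
MbraAG-29TM-muscle,adult,male,muscle,,GolfoArtabro,264,T,C,74,26.3
MbraAG-29TM-muscle,adult,male,muscle,,GolfoArtabro,303,T,C,0,100
MbraAG-29TM-muscle,adult,male,muscle,,GolfoArtabro,375,T,C,77.3,22.7
MbraAG-30TM-muscle,adult,male,muscle,,GolfoArtabro,240,T,C,27.1,72.9
MbraAG-30TM-muscle,adult,male,muscle,,GolfoArtabro,264,T,C,0,100
MbraAG-30TM-muscle,adult,male,muscle,,GolfoArtabro,303,T,C,31.3,68.7
MbraAG-30TM-muscle,adult,male,muscle,,GolfoArtabro,375,T,C,75.8,24.2
MbraRA-G1-gonad,adult,female,gonad,,RiaArousa,240,T,C,12.6,87.4
MbraRA-G1-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G1-gonad,adult,female,gonad,,RiaArousa,303,T,C,100,0
MbraRA-G1-gonad,adult,female,gonad,,RiaArousa,375,T,C,100,0
MbraRA-G2-gonad,adult,female,gonad,,RiaArousa,240,T,C,100,0
MbraRA-G2-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G2-gonad,adult,female,gonad,,RiaArousa,303,T,C,78.8,21.2
MbraRA-G2-gonad,adult,female,gonad,,RiaArousa,375,T,C,0,100
MbraRA-G4-gonad,adult,female,gonad,,RiaArousa,240,T,C,100,0
MbraRA-G4-gonad,adult,female,gonad,,RiaArousa,264,T,C,13,86.6
MbraRA-G4-gonad,adult,female,gonad,,RiaArousa,303,T,C,0,100
MbraRA-G4-gonad,adult,female,gonad,,RiaArousa,375,T,C,100,0
MbraRA-G22-gonad,adult,female,gonad,,RiaArousa,240,T,C,17.5,82.5
MbraRA-G22-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G22-gonad,adult,female,gonad,,RiaArousa,303,T,C,19.1,80.9
MbraRA-G22-gonad,adult,female,gonad,,RiaArousa,375,T,C,0,100
MbraRA-G24-gonad,adult,female,gonad,,RiaArousa,240,T,C,11.0,89.0
MbraRA-G24-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G24-gonad,adult,female,gonad,,RiaArousa,303,T,C,13.8,86.2
MbraRA-G24-gonad,adult,female,gonad,,RiaArousa,375,T,C,100,0
MbraRA-G25-gonad,adult,female,gonad,,RiaArousa,240,T,C,100,0
MbraRA-G25-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G25-gonad,adult,female,gonad,,RiaArousa,303,T,C,100,0
MbraRA-G25-gonad,adult,female,gonad,,RiaArousa,375,T,C,74.7,25.3
MbraRA-G28-gonad,adult,female,gonad,,RiaArousa,240,T,C,16.8,83.2
MbraRA-G28-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G28-gonad,adult,female,gonad,,RiaArousa,303,T,C,18.4,81.6
MbraRA-G28-gonad,adult,female,gonad,,RiaArousa,375,T,C,100,0
MbraRA-G40-gonad,adult,female,gonad,,RiaArousa,240,T,C,40.5,59.5
MbraRA-G40-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G40-gonad,adult,female,gonad,,RiaArousa,303,T,C,42.0,58.0
MbraRA-G40-gonad,adult,female,gonad,,RiaArousa,375,T,C,100,0
MbraRA-G42-gonad,adult,female,gonad,,RiaArousa,240,T,C,10.7,89.3
MbraRA-G42-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G42-gonad,adult,female,gonad,,RiaArousa,303,T,C,0,100
MbraRA-G42-gonad,adult,female,gonad,,RiaArousa,375,T,C,100,0
MbraRA-G44-gonad,adult,female,gonad,,RiaArousa,240,T,C,84.2,15.8
MbraRA-G44-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G44-gonad,adult,female,gonad,,RiaArousa,303,T,C,100,0
MbraRA-G44-gonad,adult,female,gonad,,RiaArousa,375,T,C,100,0
MbraRA-G45-gonad,adult,female,gonad,,RiaArousa,240,T,C,47.3,52.7
MbraRA-G45-gonad,adult,female,gonad,,RiaArousa,264,T,C,0,100
MbraRA-G45-gonad,adult,female,gonad,,RiaArousa,303,T,C,46.6,53.4
MbraRA-G45-gonad,adult,female,gonad,,RiaArousa,375,T,C,100,0
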