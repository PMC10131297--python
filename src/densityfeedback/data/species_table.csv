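abbr,group,mass_kg,GL_yr,q_yr
DP,herbivore_vombatiform,2786,18.1,724
PA,herbivore_vombatiform,1000,15.1,604
ZT,herbivore_vombatiform,500,13.2,528
PH,herbivore_vombatiform,200,10.7,428
VU,herbivore_vombatiform,25,10.0,400
PG,herbivore_macropodiform,250,8.3,332
SS,herbivore_macropodiform,150,8.1,324
PT,herbivore_macropodiform,130,7.8,312
SO,herbivore_macropodiform,120,7.8,312
MN,herbivore_macropodiform,55,6.0,240
OR,herbivore_macropodiform,25,5.5,220
NR,herbivore_macropodiform,14,6.3,252
GN,omnivore_bird,200,20.0,800
DN,omnivore_bird,55,5.9,236
AL,omnivore_bird,2.2,6.8,272
TC,carnivore,110,9.1,364
TH,carnivore,20,5.2,208
SH,carnivore,6.1,3.1,124
DM,carnivore,2,2.3,92
MR,invertivore_monotreme,11,16.4,656
TA,invertivore_monotreme,4,14.1,564
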