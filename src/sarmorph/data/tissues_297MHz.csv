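label,name,conductivity_S_per_m,rel_permittivity,density_kg_per_m3,t1w_mean,t1w_sd,dsc_group
0,air,0.0,1.0,0.0,0.0,0.0,air
1,skin,0.64,49.9,1109.0,620.0,20.0,skin
2,fat,0.068,11.7,911.0,900.0,25.0,fat
3,muscle,0.77,58.2,1090.0,500.0,20.0,muscle
4,skull,0.132,13.4,1908.0,250.0,15.0,bone
5,csf,2.22,72.7,1007.0,150.0,10.0,csf
6,gray_matter,0.69,60.0,1045.0,450.0,15.0,gray matter
7,white_matter,0.41,43.8,1041.0,700.0,15.0,white matter
8,cerebellum,0.97,59.7,1045.0,480.0,15.0,cerebellum
9,cortical_bone,0.132,13.4,1908.0,240.0,15.0,bone
10,cancellous_bone,0.45,23.2,1178.0,360.0,15.0,bone
11,dura,0.8,46.0,1174.0,300.0,15.0,dura
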