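region,E_GPa,nu
Trabecular Bone,0.64,0.28
Posterior Zygomatic Arch,12.5,0.28
Frontal Torus,13.1,0.25
Glabella,14.4,0.27
Medial Orbital Wall,14.6,0.36
Frontal Squama,14.9,0.31
Anterior Palate,15.3,0.34
P3-M1 Alveolus,16.7,0.25
Neuro- and Basi- crania,17.3,0.28
Root of Zygoma,17.9,0.34
Lateral Rostrum,18.1,0.25
Premaxilla,18.5,0.21
Posterior Palate,18.8,0.32
Postorbital bar,19.8,0.27
Dorsal Rostrum,19.9,0.22
M2-M3 Alveolus,20.6,0.27
Anterior Zygomatic Arch,20.8,0.26
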