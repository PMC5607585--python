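name,material,shape,width_mm,length_mm,orientation,apparent_width_factor,apparent_length_factor
Gold Anchor 0.28x10,gold_iron,cylinder,0.28,10,parallel_B0,4.2,2.0
Gold Anchor 0.28x20,gold_iron,cylinder,0.28,20,parallel_B0,4.2,2.0
Gold Anchor 0.4x20,gold_iron,cylinder,0.4,20,parallel_B0,4.2,2.0
Gold Anchor 1.3x1.3,gold_iron,sphere,1.3,1.3,parallel_B0,4.2,4.2
Gold Anchor 1.8x1.8,gold_iron,sphere,1.8,1.8,parallel_B0,4.2,4.2
Gold Anchor 2.1x2.1,gold_iron,sphere,2.1,2.1,parallel_B0,4.2,4.2
Visicoil 0.35x5,gold,cylinder,0.35,5,parallel_B0,4.2,2.0
Visicoil 0.35x30,gold,cylinder,0.35,30,parallel_B0,4.2,2.0
Visicoil 0.5x5,gold,cylinder,0.5,5,parallel_B0,4.2,2.0
Visicoil 0.75x10,brass,cylinder,0.75,10,parallel_B0,4.2,2.0
Visicoil 1.1x10,gold,cylinder,1.1,10,parallel_B0,3.18,1.0
Visicoil 1.1x10 V,gold,cylinder,1.1,10,orthogonal_B0,5.91,1.0
BiomarC 1x3,carbon_coated,cylinder,1.0,3,parallel_B0,4.2,2.0
BiomarC 1x5,carbon_coated,cylinder,1.0,5,parallel_B0,4.2,2.0
BiomarC 2x4,carbon_coated,cylinder,2.0,4,parallel_B0,4.2,2.0
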