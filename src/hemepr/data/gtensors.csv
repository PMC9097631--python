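label,gz,gy,gx,sgz,sgy,sgx,strain_z,strain_y,strain_x,lw_mT
CYP116B5hd,2.44,2.25,1.92,0.005,0.002,0.002,0.040,0.0080,0.010,2
CYP116B5hd+Imidazole,2.47,2.26,1.90,0.005,0.002,0.002,0.042,0.0099,0.020,1
CYP116B5hd+Histidine,2.42,2.24,1.92,0.005,0.002,0.002,0.038,0.0140,0.017,2
CYPBM3hd,2.42,2.26,1.92,0.005,0.002,0.002,0.020,0.0001,0.001,3
CYPBM3hd+Imidazole,2.45,2.26,1.90,0.005,0.002,0.002,0.050,0.0005,0.020,1
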