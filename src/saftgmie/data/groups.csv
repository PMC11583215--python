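name,nu_star,shape_factor,sigma_A,sigma_born_A,lambda_r,lambda_a,epsilon_K,charge,n_H,n_e1,n_e2
H2O,1,1.0000,3.0063,,17.020,6,266.68,0,2,2,0
COOH,1,0.55593,4.3331,,8.0000,6,405.78,0,1,2,2
NH2,1,0.79675,3.2477,,10.254,6,284.78,0,2,1,0
CH3,1,0.57255,4.0772,,15.050,6,256.77,0,0,0,0
CH2,1,0.22932,4.8801,,19.871,6,473.39,0,0,0,0
CH,1,0.072100,5.2950,,8.0000,6,95.621,0,0,0,0
CH2OH,2,0.58538,3.4054,,22.699,6,407.22,0,1,2,0
CHOH,2,0.18963,4.5381,,18.185,6,599.66,0,1,2,0
CONH,2,0.73764,2.9482,,29.839,6,156.12,0,1,2,0
COO-,1,0.55593,4.3331,4.6364,8.0000,6,21.264,-1,0,4,0
NH3+,1,0.79675,3.2477,3.4750,10.254,6,48.300,1,3,0,0
H3O+,1,1.0000,3.0063,3.0063,17.020,6,68.190,1,3,0,0
OH-,1,1.0000,2.4600,3.0063,17.020,6,170.24,-1,0,3,0
Na+,1,1.0000,2.3200,3.3600,12.000,6,31.711,1,0,0,0
Cl-,1,1.0000,3.3400,3.8740,12.000,6,113.77,-1,0,0,0
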