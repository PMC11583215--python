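group_k,site_a,group_l,site_b,eps_HB_K,K_HB_A3,provenance
H2O,H,H2O,e1,1985.4,101.69,fitted
H2O,e1,COOH,H,2567.7,270.09,fitted
H2O,H,COOH,e1,1451.8,280.89,fitted
H2O,H,COOH,e2,1252.6,150.98,fitted
H2O,H,NH2,e1,1460.0,179.60,fitted
H2O,e1,NH2,H,1988.3,55.824,fitted
H2O,H,CH2OH,e1,2153.2,147.40,fitted
H2O,e1,CH2OH,H,621.68,425.00,fitted
H2O,H,CHOH,e1,2140.9,19.478,fitted
H2O,e1,CHOH,H,2289.1,63.813,fitted
H2O,H,COO-,e1,802.21,52.555,fitted
H2O,e1,NH3+,H,2016.6,49.397,fitted
H2O,e1,H3O+,H,1985.4,101.69,fitted
H2O,H,OH-,e1,1492.0,76.411,fitted
H2O,H,CONH,e1,1986.2,236.59,fitted
H2O,e1,CONH,H,3061.5,130.81,fitted
COOH,H,COOH,H,6427.9,0.80620,fitted
COOH,H,NH2,e1,4000.0,100.00,fitted
COOH,e1,NH2,H,1446.6,100.00,fitted
COOH,e2,NH2,H,1220.1,100.00,fitted
COOH,H,CH2OH,e1,3238.4,36.050,fitted
COOH,e1,CH2OH,H,1062.1,210.67,fitted
COOH,e2,CH2OH,H,997.89,227.07,fitted
COOH,H,CHOH,e1,4000.0,10.834,fitted
COOH,e1,CHOH,H,305.02,1.0000,fitted
COOH,e2,CHOH,H,319.87,0.10000,fitted
COOH,e1,NH3+,H,334.08,13.500,fitted
COOH,e2,NH3+,H,366.54,9990.0,fitted
COOH,e1,H3O+,H,1451.8,280.89,fitted
COOH,e2,H3O+,H,1252.6,150.98,fitted
COOH,H,OH-,e1,2036.0,214.16,fitted
COOH,H,CONH,e1,2487.2,242.73,fitted
COOH,e1,CONH,H,1723.5,461.80,fitted
COOH,e2,CONH,H,1723.5,461.80,fitted
NH2,e1,NH2,H,1070.8,95.225,fitted
NH2,H,CH2OH,e1,629.88,346.08,fitted
NH2,e1,CH2OH,H,2403.8,26.192,fitted
NH2,H,CHOH,e1,1524.9,103.22,fitted
NH2,e1,CHOH,H,1470.3,303.47,fitted
NH2,H,COO-,e1,1220.1,100.00,fitted
NH2,e1,NH3+,H,1070.8,95.225,fitted
NH2,e1,H3O+,H,1460.0,179.60,fitted
NH2,H,OH-,e1,1511.4,42.436,fitted
NH2,e1,CONH,H,2807.1,122.83,fitted
NH2,H,CONH,e1,1687.6,122.83,fitted
CH2OH,H,CH2OH,e1,2097.9,62.309,fitted
CH2OH,H,CHOH,e1,2500.0,10.444,fitted
CH2OH,e1,CHOH,H,1464.1,591.55,fitted
CH2OH,H,CONH,e1,CR,CR,CR
CH2OH,e1,CONH,H,CR,CR,CR
CHOH,H,CHOH,e1,2480.6,8.4740,fitted
COO-,e1,NH3+,H,1767.0,13.500,fitted
COO-,e1,H3O+,H,802.21,52.555,fitted
NH3+,H,OH-,e1,1988.3,55.824,fitted
H3O+,H,OH-,e1,1492.0,76.411,fitted
CONH,H,CONH,e1,3181.7,155.31,fitted
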