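group_k,group_l,epsilon_K,lambda_r,provenance
H2O,COOH,289.76,CR,fitted
H2O,NH2,358.55,CR,fitted
H2O,CH3,358.18,100.00,fitted
H2O,CH2,423.63,100.00,fitted
H2O,CH,275.75,CR,fitted
H2O,CH2OH,353.37,CR,fitted
H2O,CHOH,479.16,CR,fitted
H2O,COO-,171.61,CR,fitted
H2O,NH3+,450.21,CR,fitted
H2O,H3O+,391.04,CR,fitted
H2O,OH-,134.41,CR,fitted
H2O,CONH,379.59,CR,fitted
H2O,Na+,539.68,CR,fitted
H2O,Cl-,95.406,CR,fitted
COOH,NH2,285.00,CR,fitted
COOH,CH3,255.99,CR,fitted
COOH,CH2,413.74,CR,fitted
COOH,CH,504.99,CR,fitted
COOH,CH2OH,488.18,CR,fitted
COOH,CHOH,1154.3,50.000,fitted
COOH,COO-,405.78,8.0000,fitted
COOH,NH3+,388.58,CR,fitted
COOH,H3O+,CR,CR,CR
COOH,OH-,CR,CR,CR
COOH,CONH,670.04,CR,fitted
COOH,Na+,CR,CR,CR
COOH,Cl-,CR,CR,CR
NH2,CH3,244.15,CR,fitted
NH2,CH2,348.39,CR,fitted
NH2,CH,278.26,CR,fitted
NH2,CH2OH,528.21,52.305,fitted
NH2,CHOH,415.54,10.643,fitted
NH2,COO-,CR,CR,CR
NH2,NH3+,284.78,CR,fitted
NH2,H3O+,CR,CR,CR
NH2,OH-,CR,CR,CR
NH2,CONH,150.77,CR,fitted
NH2,Na+,CR,CR,CR
NH2,Cl-,CR,CR,CR
CH3,CH2,350.77,CR,fitted
CH3,CH,387.48,CR,fitted
CH3,CH2OH,333.20,CR,fitted
CH3,CHOH,479.38,CR,fitted
CH3,COO-,255.99,CR,fitted
CH3,NH3+,244.15,CR,fitted
CH3,H3O+,CR,CR,CR
CH3,Na+,CR,CR,CR
CH3,Cl-,CR,CR,CR
CH3,OH-,CR,CR,CR
CH3,CONH,430.60,CR,fitted
CH2,CH,506.21,CR,fitted
CH2,CH2OH,423.17,CR,fitted
CH2,CHOH,517.64,CR,fitted
CH2,COO-,413.74,CR,fitted
CH2,NH3+,348.39,CR,fitted
CH2,H3O+,CR,CR,CR
CH2,OH-,CR,CR,CR
CH2,CONH,315.00,CR,fitted
CH2,Na+,CR,CR,CR
CH2,Cl-,CR,CR,CR
CH,CH2OH,329.22,CR,fitted
CH,CHOH,0,CR,fitted
CH,COO-,504.99,CR,fitted
CH,NH3+,151.01,CR,fitted
CH,H3O+,CR,CR,CR
CH,OH-,CR,CR,CR
CH,CONH,CR,CR,CR
CH,Na+,CR,CR,CR
CH,Cl-,CR,CR,CR
CH2OH,CHOH,389.23,CR,fitted
CH2OH,CONH,CR,CR,CR
COO-,NH3+,26.330,CR,fitted
COO-,H3O+,27.740,CR,fitted
COO-,OH-,44.520,CR,fitted
COO-,Na+,9.9125,CR,fitted
COO-,Cl-,21.265,CR,fitted
NH3+,H3O+,56.958,CR,fitted
NH3+,OH-,62.238,CR,fitted
NH3+,Na+,CR,CR,CR
NH3+,Cl-,65.257,CR,fitted
H3O+,OH-,66.439,CR,fitted
H3O+,Na+,37.480,CR,fitted
H3O+,Cl-,70.552,CR,fitted
OH-,Na+,27.898,CR,fitted
OH-,Cl-,123.21,CR,fitted
Na+,Cl-,27.938,CR,fitted
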