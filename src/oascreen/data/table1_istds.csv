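name,base_formula,n_deuterium,n_carbon13,rt,conc_um
D3-propionylglycine,C5H9NO3,3,0,2.33,25.0
13C5-oxoglutaric acid,C5H6O5,0,5,1.19,25.0
13C4-3-hydroxybutyric acid,C4H8O3,0,4,2.56,25.0
D4-adipic acid,C6H10O4,4,0,4.93,25.0
D2-glycolic acid,C2H4O3,2,0,0.78,25.0
D4-glutaric acid,C5H8O4,4,0,4.11,25.0
D4-citric acid,C6H8O7,4,0,1.88,25.0
D5-ethylmalonic acid,C5H8O4,5,0,4.58,25.0
D3-glyceric acid,C3H6O4,3,0,0.76,25.0
D3-malic acid,C4H6O5,3,0,1.04,25.0
D3-hexanoylglycine,C8H15NO3,3,0,6.86,25.0
D4-sebacic acid,C10H18O4,4,0,9.05,25.0
D3-methylmalonic acid,C4H6O4,3,0,2.89,25.0
D3-3-hydroxy-3-methylglutaric acid,C6H10O5,3,0,3.68,25.0
13C3-lactic acid,C3H6O3,0,3,1.18,25.0
D3-methylcitric acid,C7H10O7,3,0,3.92,25.0
D5-pyroglutamic acid,C5H7NO3,5,0,1.84,25.0
13C3-pyruvic acid,C3H4O3,0,3,0.91,25.0
13C5-succinylacetone,C7H10O4,0,5,4.50,25.0
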