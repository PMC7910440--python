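isotope,parent_element,abundance_mass_fraction,atomic_mass_g_mol,half_life_yr,E_alpha_MeV,E_beta_MeV,E_gamma_MeV,provenance
U238,U,0.992742,238.0508,4.468e9,42.97,6.04,1.77,"natural-U isotopic composition and half-life from standard nuclear-data compilations (CIAAW / ENSDF); chain sums to Pb-206 at secular equilibrium, mean (absorbed) beta energies, neutrinos excluded"
U235,U,0.007204,235.0439,7.04e8,42.30,1.08,0.51,"natural-U isotopic composition; chain sums to Pb-207 at secular equilibrium from standard decay data"
Th232,Th,1.0,232.0381,1.405e10,35.95,2.83,2.47,"Th is mono-isotopic; chain sums to Pb-208 at secular equilibrium from standard decay data"
K40,K,0.000117,39.9640,1.248e9,0.0,0.523,0.156,"K-40 fraction of natural K; beta branch 89.3% (mean beta 0.585 MeV), EC/gamma branch 10.7% (1.461 MeV); no alpha branch"
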