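lithology,U_ppm,Th_ppm,K2O_wt_pct,grain_density_g_cm3,phi0,provenance
abyssal_clay,2.6,13.4,3.01,2.75,0.83,"pelagic-clay U/Th/K typical of ocean-basin compilations (Li & Schoonmaker-type values); terrigenous-clay grain density; South Pacific Gyre abyssal-clay seafloor porosity"
calcareous_ooze,0.8,1.5,0.40,2.71,0.65,"carbonate-dominated pelagic sediment; calcite grain density"
siliceous_ooze,1.5,5.0,1.50,2.30,0.80,"clay-bearing diatom ooze; opal-rich grain density"
calcareous_marl,1.7,7.0,1.70,2.73,0.70,"nannofossil-bearing clay, intermediate between clay and carbonate end members"
lithogenous,2.8,10.7,3.37,2.65,0.60,"upper-continental-crust U/Th/K for terrigenous margin sediment; quartz-dominated grain density"
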