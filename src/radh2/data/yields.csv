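medium,radiation,G_mean,G_sd,G_max,n_samples,provenance
pure_water,alpha,1.30,0.13,,3,"air-saturated deionized water, Po-210 alpha source; agrees with cyclotron He2+ value 1.30 +/- 0.13"
pure_water,gamma,0.45,0.05,,3,"Cs-137 gamma source, deionized water; agrees with published high-dose-rate pure-water value"
seawater,alpha,1.30,0.13,,3,"North Atlantic bottom water; indistinguishable from pure water at 90% confidence"
seawater,gamma,0.45,0.05,,3,"North Atlantic bottom water; indistinguishable from pure water at 90% confidence"
abyssal_clay,alpha,16.9,1.7,35.1,11,"lithology mean reconstructed as 13x pure-water alpha yield (clay amplification exceeds one order of magnitude; per-sample maximum 27x); per-sample rows not recoverable"
abyssal_clay,gamma,1.80,0.18,,11,"lithology mean reconstructed as 4x pure-water gamma yield"
siliceous_ooze,alpha,19.5,2.0,,3,"clay-bearing siliceous ooze; mean amplification 15x pure-water alpha yield"
siliceous_ooze,gamma,3.60,0.36,,3,"mean amplification 8x pure-water gamma yield"
calcareous_marl,alpha,15.6,1.6,,2,"nannofossil-bearing clay; mean amplification 12x pure-water alpha yield"
calcareous_marl,gamma,0.90,0.09,,2,"mean amplification 2x pure-water gamma yield"
calcareous_ooze,alpha,6.50,0.65,,2,"mean amplification 5x pure-water alpha yield"
calcareous_ooze,gamma,0.90,0.09,,2,"mean amplification 2x pure-water gamma yield"
lithogenous,alpha,6.50,0.65,,2,"no lithology-mean amplification printed for lithogenous sediment; assigned the conservative calcareous-ooze factor (5x); override encouraged"
lithogenous,gamma,0.90,0.09,,2,"assigned 2x pure-water gamma yield (see alpha row)"
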