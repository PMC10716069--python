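label,kind,mean,sd,n,mu0,r_obs,r_xx,r_yy
desktop_pointing1_vs_chance,one_sample,73.71,23.22,57,90,,,
immersive_pointing1_vs_chance,one_sample,64.58,27.45,48,90,,,
desktop_efficiency_vs_learned_route,one_sample,1.81,0.39,57,2.54,,,
immersive_efficiency_vs_learned_route,one_sample,1.56,0.39,48,2.19,,,
desktop_low_pointing1_vs_chance,one_sample,86.32,13.01,37,90,,,
desktop_low_efficiency_vs_learned_route,one_sample,2.04,0.24,37,2.54,,,
immersive_low_pointing1_vs_chance,one_sample,85.14,11.16,24,90,,,
immersive_low_efficiency_vs_learned_route,one_sample,1.89,0.28,24,2.19,,,
desktop_efficiency_pointing1,disattenuate,,,,,0.71,0.72,0.83
desktop_efficiency_pointing2,disattenuate,,,,,0.76,0.72,0.84
desktop_pointing1_pointing2,disattenuate,,,,,0.78,0.83,0.84
immersive_efficiency_pointing1,disattenuate,,,,,0.74,0.87,0.87
immersive_efficiency_pointing2,disattenuate,,,,,0.79,0.87,0.90
immersive_pointing1_pointing2,disattenuate,,,,,0.78,0.87,0.90
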