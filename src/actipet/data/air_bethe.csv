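# material: air
# density_g_cm3: 0.00120479
# provenance: computed from the Bethe stopping-power formula (no shell/Barkas corrections) with ICRU-49 mean excitation energy I = 85.7 eV and Z/A = 0.49919; see scripts/make_stopping_tables.py
energy_MeV,mass_sp_MeV_cm2_per_g
3.000000e-01,4.871038e+02
3.094453e-01,4.794469e+02
3.191881e-01,4.718039e+02
3.292375e-01,4.641811e+02
3.396034e-01,4.565845e+02
3.502956e-01,4.490195e+02
3.613245e-01,4.414912e+02
3.727006e-01,4.340045e+02
3.844349e-01,4.265639e+02
3.965386e-01,4.191735e+02
4.090234e-01,4.118372e+02
4.219013e-01,4.045586e+02
4.351846e-01,3.973410e+02
4.488862e-01,3.901874e+02
4.630191e-01,3.831007e+02
4.775970e-01,3.760835e+02
4.926339e-01,3.691381e+02
5.081442e-01,3.622667e+02
5.241428e-01,3.554712e+02
5.406452e-01,3.487534e+02
5.576671e-01,3.421149e+02
5.752250e-01,3.355572e+02
5.933356e-01,3.290814e+02
6.120165e-01,3.226888e+02
6.312855e-01,3.163802e+02
6.511611e-01,3.101564e+02
6.716626e-01,3.040183e+02
6.928095e-01,2.979663e+02
7.146223e-01,2.920009e+02
7.371218e-01,2.861225e+02
7.603296e-01,2.803314e+02
7.842682e-01,2.746276e+02
8.089605e-01,2.690113e+02
8.344302e-01,2.634823e+02
8.607017e-01,2.580408e+02
8.878005e-01,2.526863e+02
9.157524e-01,2.474188e+02
9.445844e-01,2.422378e+02
9.743241e-01,2.371431e+02
1.005000e+00,2.321342e+02
1.036642e+00,2.272105e+02
1.069280e+00,2.223716e+02
1.102946e+00,2.176169e+02
1.137672e+00,2.129457e+02
1.173490e+00,2.083574e+02
1.210437e+00,2.038513e+02
1.248547e+00,1.994266e+02
1.287857e+00,1.950826e+02
1.328404e+00,1.908184e+02
1.370229e+00,1.866333e+02
1.413369e+00,1.825264e+02
1.457869e+00,1.784968e+02
1.503769e+00,1.745436e+02
1.551114e+00,1.706660e+02
1.599950e+00,1.668630e+02
1.650324e+00,1.631336e+02
1.702283e+00,1.594769e+02
1.755879e+00,1.558920e+02
1.811162e+00,1.523779e+02
1.868185e+00,1.489336e+02
1.927004e+00,1.455581e+02
1.987675e+00,1.422504e+02
2.050255e+00,1.390096e+02
2.114807e+00,1.358346e+02
2.181390e+00,1.327244e+02
2.250070e+00,1.296781e+02
2.320912e+00,1.266947e+02
2.393985e+00,1.237731e+02
2.469358e+00,1.209124e+02
2.547105e+00,1.181115e+02
2.627299e+00,1.153695e+02
2.710018e+00,1.126855e+02
2.795341e+00,1.100583e+02
2.883351e+00,1.074872e+02
2.974132e+00,1.049710e+02
3.067771e+00,1.025088e+02
3.164358e+00,1.000998e+02
3.263986e+00,9.774283e+01
3.366751e+00,9.543711e+01
3.472751e+00,9.318166e+01
3.582089e+00,9.097558e+01
3.694869e+00,8.881794e+01
3.811200e+00,8.670786e+01
3.931194e+00,8.464444e+01
4.054965e+00,8.262681e+01
4.182634e+00,8.065409e+01
4.314322e+00,7.872543e+01
4.450156e+00,7.683997e+01
4.590266e+00,7.499689e+01
4.734788e+00,7.319535e+01
4.883861e+00,7.143453e+01
5.037626e+00,6.971365e+01
5.196233e+00,6.803189e+01
5.359834e+00,6.638848e+01
5.528585e+00,6.478265e+01
5.702650e+00,6.321364e+01
5.882195e+00,6.168070e+01
6.067392e+00,6.018309e+01
6.258421e+00,5.872009e+01
6.455464e+00,5.729098e+01
6.658711e+00,5.589507e+01
6.868357e+00,5.453166e+01
7.084603e+00,5.320006e+01
7.307658e+00,5.189962e+01
7.537736e+00,5.062967e+01
7.775057e+00,4.938957e+01
8.019851e+00,4.817869e+01
8.272351e+00,4.699639e+01
8.532802e+00,4.584206e+01
8.801453e+00,4.471511e+01
9.078562e+00,4.361493e+01
9.364395e+00,4.254095e+01
9.659228e+00,4.149261e+01
9.963344e+00,4.046932e+01
1.027703e+01,3.947056e+01
1.060060e+01,3.849577e+01
1.093436e+01,3.754443e+01
1.127862e+01,3.661602e+01
1.163372e+01,3.571002e+01
1.200000e+01,3.482595e+01
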