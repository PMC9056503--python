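# material: water
# density_g_cm3: 1.0
# provenance: computed from the Bethe stopping-power formula (no shell/Barkas corrections) with ICRU-49 mean excitation energy I = 75.0 eV and Z/A = 0.55509; see scripts/make_stopping_tables.py
energy_MeV,mass_sp_MeV_cm2_per_g
3.000000e-01,5.772163e+02
3.094453e-01,5.676169e+02
3.191881e-01,5.580661e+02
3.292375e-01,5.485699e+02
3.396034e-01,5.391338e+02
3.502956e-01,5.297631e+02
3.613245e-01,5.204626e+02
3.727006e-01,5.112366e+02
3.844349e-01,5.020894e+02
3.965386e-01,4.930246e+02
4.090234e-01,4.840459e+02
4.219013e-01,4.751563e+02
4.351846e-01,4.663589e+02
4.488862e-01,4.576563e+02
4.630191e-01,4.490508e+02
4.775970e-01,4.405447e+02
4.926339e-01,4.321400e+02
5.081442e-01,4.238383e+02
5.241428e-01,4.156413e+02
5.406452e-01,4.075502e+02
5.576671e-01,3.995662e+02
5.752250e-01,3.916904e+02
5.933356e-01,3.839236e+02
6.120165e-01,3.762664e+02
6.312855e-01,3.687195e+02
6.511611e-01,3.612832e+02
6.716626e-01,3.539578e+02
6.928095e-01,3.467434e+02
7.146223e-01,3.396402e+02
7.371218e-01,3.326480e+02
7.603296e-01,3.257667e+02
7.842682e-01,3.189961e+02
8.089605e-01,3.123358e+02
8.344302e-01,3.057853e+02
8.607017e-01,2.993443e+02
8.878005e-01,2.930120e+02
9.157524e-01,2.867880e+02
9.445844e-01,2.806714e+02
9.743241e-01,2.746615e+02
1.005000e+00,2.687575e+02
1.036642e+00,2.629586e+02
1.069280e+00,2.572638e+02
1.102946e+00,2.516722e+02
1.137672e+00,2.461828e+02
1.173490e+00,2.407946e+02
1.210437e+00,2.355065e+02
1.248547e+00,2.303174e+02
1.287857e+00,2.252262e+02
1.328404e+00,2.202318e+02
1.370229e+00,2.153330e+02
1.413369e+00,2.105286e+02
1.457869e+00,2.058174e+02
1.503769e+00,2.011983e+02
1.551114e+00,1.966700e+02
1.599950e+00,1.922312e+02
1.650324e+00,1.878808e+02
1.702283e+00,1.836174e+02
1.755879e+00,1.794398e+02
1.811162e+00,1.753468e+02
1.868185e+00,1.713370e+02
1.927004e+00,1.674093e+02
1.987675e+00,1.635623e+02
2.050255e+00,1.597947e+02
2.114807e+00,1.561054e+02
2.181390e+00,1.524931e+02
2.250070e+00,1.489564e+02
2.320912e+00,1.454942e+02
2.393985e+00,1.421052e+02
2.469358e+00,1.387881e+02
2.547105e+00,1.355418e+02
2.627299e+00,1.323650e+02
2.710018e+00,1.292565e+02
2.795341e+00,1.262150e+02
2.883351e+00,1.232395e+02
2.974132e+00,1.203286e+02
3.067771e+00,1.174813e+02
3.164358e+00,1.146964e+02
3.263986e+00,1.119726e+02
3.366751e+00,1.093090e+02
3.472751e+00,1.067043e+02
3.582089e+00,1.041574e+02
3.694869e+00,1.016673e+02
3.811200e+00,9.923284e+01
3.931194e+00,9.685294e+01
4.054965e+00,9.452656e+01
4.182634e+00,9.225266e+01
4.314322e+00,9.003020e+01
4.450156e+00,8.785815e+01
4.590266e+00,8.573553e+01
4.734788e+00,8.366133e+01
4.883861e+00,8.163459e+01
5.037626e+00,7.965435e+01
5.196233e+00,7.771965e+01
5.359834e+00,7.582956e+01
5.528585e+00,7.398317e+01
5.702650e+00,7.217958e+01
5.882195e+00,7.041790e+01
6.067392e+00,6.869725e+01
6.258421e+00,6.701677e+01
6.455464e+00,6.537561e+01
6.658711e+00,6.377296e+01
6.868357e+00,6.220798e+01
7.084603e+00,6.067988e+01
7.307658e+00,5.918787e+01
7.537736e+00,5.773117e+01
7.775057e+00,5.630901e+01
8.019851e+00,5.492066e+01
8.272351e+00,5.356538e+01
8.532802e+00,5.224244e+01
8.801453e+00,5.095114e+01
9.078562e+00,4.969078e+01
9.364395e+00,4.846068e+01
9.659228e+00,4.726018e+01
9.963344e+00,4.608861e+01
1.027703e+01,4.494533e+01
1.060060e+01,4.382971e+01
1.093436e+01,4.274113e+01
1.127862e+01,4.167898e+01
1.163372e+01,4.064267e+01
1.200000e+01,3.963161e+01
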