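# material: kapton
# density_g_cm3: 1.42
# provenance: computed from the Bethe stopping-power formula (no shell/Barkas corrections) with ICRU-49 mean excitation energy I = 79.6 eV and Z/A = 0.51264; see scripts/make_stopping_tables.py
energy_MeV,mass_sp_MeV_cm2_per_g
3.000000e-01,5.184137e+02
3.094453e-01,5.099957e+02
3.191881e-01,5.016089e+02
3.292375e-01,4.932593e+02
3.396034e-01,4.849524e+02
3.502956e-01,4.766934e+02
3.613245e-01,4.684872e+02
3.727006e-01,4.603381e+02
3.844349e-01,4.522504e+02
3.965386e-01,4.442279e+02
4.090234e-01,4.362742e+02
4.219013e-01,4.283925e+02
4.351846e-01,4.205859e+02
4.488862e-01,4.128572e+02
4.630191e-01,4.052087e+02
4.775970e-01,3.976429e+02
4.926339e-01,3.901619e+02
5.081442e-01,3.827675e+02
5.241428e-01,3.754613e+02
5.406452e-01,3.682450e+02
5.576671e-01,3.611198e+02
5.752250e-01,3.540869e+02
5.933356e-01,3.471473e+02
6.120165e-01,3.403019e+02
6.312855e-01,3.335513e+02
6.511611e-01,3.268963e+02
6.716626e-01,3.203371e+02
6.928095e-01,3.138742e+02
7.146223e-01,3.075079e+02
7.371218e-01,3.012382e+02
7.603296e-01,2.950652e+02
7.842682e-01,2.889888e+02
8.089605e-01,2.830089e+02
8.344302e-01,2.771253e+02
8.607017e-01,2.713376e+02
8.878005e-01,2.656455e+02
9.157524e-01,2.600486e+02
9.445844e-01,2.545463e+02
9.743241e-01,2.491381e+02
1.005000e+00,2.438234e+02
1.036642e+00,2.386014e+02
1.069280e+00,2.334716e+02
1.102946e+00,2.284331e+02
1.137672e+00,2.234851e+02
1.173490e+00,2.186269e+02
1.210437e+00,2.138575e+02
1.248547e+00,2.091761e+02
1.287857e+00,2.045817e+02
1.328404e+00,2.000734e+02
1.370229e+00,1.956503e+02
1.413369e+00,1.913112e+02
1.457869e+00,1.870553e+02
1.503769e+00,1.828815e+02
1.551114e+00,1.787887e+02
1.599950e+00,1.747759e+02
1.650324e+00,1.708420e+02
1.702283e+00,1.669859e+02
1.755879e+00,1.632066e+02
1.811162e+00,1.595030e+02
1.868185e+00,1.558740e+02
1.927004e+00,1.523185e+02
1.987675e+00,1.488353e+02
2.050255e+00,1.454234e+02
2.114807e+00,1.420817e+02
2.181390e+00,1.388090e+02
2.250070e+00,1.356043e+02
2.320912e+00,1.324665e+02
2.393985e+00,1.293945e+02
2.469358e+00,1.263872e+02
2.547105e+00,1.234435e+02
2.627299e+00,1.205623e+02
2.710018e+00,1.177425e+02
2.795341e+00,1.149832e+02
2.883351e+00,1.122832e+02
2.974132e+00,1.096415e+02
3.067771e+00,1.070570e+02
3.164358e+00,1.045288e+02
3.263986e+00,1.020558e+02
3.366751e+00,9.963693e+01
3.472751e+00,9.727128e+01
3.582089e+00,9.495782e+01
3.694869e+00,9.269559e+01
3.811200e+00,9.048361e+01
3.931194e+00,8.832092e+01
4.054965e+00,8.620658e+01
4.182634e+00,8.413967e+01
4.314322e+00,8.211924e+01
4.450156e+00,8.014441e+01
4.590266e+00,7.821426e+01
4.734788e+00,7.632792e+01
4.883861e+00,7.448451e+01
5.037626e+00,7.268318e+01
5.196233e+00,7.092307e+01
5.359834e+00,6.920335e+01
5.528585e+00,6.752319e+01
5.702650e+00,6.588180e+01
5.882195e+00,6.427837e+01
6.067392e+00,6.271211e+01
6.258421e+00,6.118226e+01
6.455464e+00,5.968806e+01
6.658711e+00,5.822875e+01
6.868357e+00,5.680360e+01
7.084603e+00,5.541190e+01
7.307658e+00,5.405293e+01
7.537736e+00,5.272599e+01
7.775057e+00,5.143039e+01
8.019851e+00,5.016547e+01
8.272351e+00,4.893056e+01
8.532802e+00,4.772501e+01
8.801453e+00,4.654819e+01
9.078562e+00,4.539946e+01
9.364395e+00,4.427821e+01
9.659228e+00,4.318384e+01
9.963344e+00,4.211576e+01
1.027703e+01,4.107338e+01
1.060060e+01,4.005613e+01
1.093436e+01,3.906346e+01
1.127862e+01,3.809481e+01
1.163372e+01,3.714965e+01
1.200000e+01,3.622744e+01
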