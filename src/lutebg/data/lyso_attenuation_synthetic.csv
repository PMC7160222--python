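# Synthetic LYSO (Lu1.8Y0.2SiO5, 7.1 g/cm3) photon mass attenuation
# coefficients, cm^2/g. See lutebg.nuclear_data for provenance notes.
energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g,total_cm2g
10.00,82.8926,0.165899,5.83601,88.8945
12.00,56.9297,0.16469,4.86334,61.9577
15.00,36.0079,0.162918,3.89067,40.0615
17.02,27.7008,0.161754,3.42891,31.2915
17.06,29.3834,0.161731,3.42087,32.966
20.00,20.9822,0.160076,2.91801,24.0603
25.00,13.1625,0.157361,2.3344,15.6542
30.00,9.01102,0.154767,1.94534,11.1111
35.00,6.52461,0.152286,1.45143,8.12833
40.00,4.93611,0.149909,1.12619,6.2122
45.00,3.8702,0.147631,0.900371,4.91821
50.00,3.11461,0.145446,0.737025,3.99708
55.00,2.56725,0.143347,0.614945,3.32554
60.00,2.15253,0.141331,0.52124,2.8151
63.30,1.92849,0.140042,0.470824,2.53935
63.33,9.98764,0.14003,0.4704,10.5981
66.00,8.86141,0.139012,0.434902,9.43533
70.00,7.47252,0.137524,0.388901,7.99895
75.00,5.90889,0.135725,0.341121,6.38574
80.00,4.74384,0.133991,0.301755,5.17958
88.00,3.79392,0.131343,0.251772,4.17704
95.00,3.0165,0.129143,0.217696,3.36334
100.00,2.58682,0.127635,0.197481,2.91194
110.00,2.01321,0.124765,0.16477,2.30275
120.00,1.60138,0.122072,0.139663,1.86312
135.00,1.17477,0.118332,0.111658,1.40476
150.00,0.890433,0.114906,0.0914012,1.09674
170.00,0.638699,0.11076,0.0720564,0.821515
200.00,0.414884,0.10529,0.0529137,0.573088
230.00,0.286741,0.100548,0.0405735,0.427862
260.00,0.207373,0.0963855,0.0321422,0.335901
300.00,0.142065,0.0915533,0.0244903,0.258108
307.00,0.134028,0.0907789,0.0234403,0.248247
340.00,0.103573,0.0873709,0.019307,0.210251
380.00,0.0782154,0.0837024,0.0156292,0.177547
420.00,0.061006,0.0804483,0.0129227,0.154377
460.00,0.0488669,0.0775338,0.0108714,0.137272
500.00,0.0398747,0.074902,0.0092786,0.124055
511.00,0.037921,0.0742216,0.00890278,0.121045
560.00,0.0306954,0.0713894,0.00748114,0.109566
620.00,0.0243275,0.0683014,0.00616568,0.0987945
700.00,0.018552,0.0647054,0.00489597,0.0881534
800.00,0.0137684,0.060861,0.00379887,0.0784282
900.00,0.0107906,0.0575704,0.00303714,0.0713982
1000.00,0.00867706,0.0547086,0.00248614,0.0658718
1100.00,0.007258,0.0521876,0.00207434,0.0615199
1200.00,0.00616616,0.0499433,0.00175825,0.0578677
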