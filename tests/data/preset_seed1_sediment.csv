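estuary,site,habitat,plot,mud_pct,grain_phi,tom_pct,chla,phaeo,plant_biomass
BEN,S1,V,P1,60.66205669281764,5.63377181759129,10.332907248226238,2.0109536238552455,8.875273751750196,406.87614024475926
BEN,S1,V,P2,71.87768391105229,5.483869924134747,9.851569857474233,3.869606378374161,8.074596526796283,343.9271077987687
BEN,S1,V,P3,80.7197825690466,4.885300799975076,8.050038720372523,5.769266170377883,9.328776888091483,251.61913616884397
BEN,S1,NV,P1,65.8624211793723,4.68218573840599,7.328849413942873,6.272733097559709,6.2272041415756645,31.160525511327826
BEN,S1,NV,P2,82.47617752711649,5.291809175273892,6.297373583055923,5.328412409045222,4.299594407989737,94.1985094184184
BEN,S1,NV,P3,64.51729529877176,5.255787290194692,7.639185537721497,5.429965861619713,6.359557723770593,11.017481233303723
BEN,S2,V,P1,56.951130212424715,5.32295971044784,8.528809754449757,3.872802798663516,10.900545707817024,304.28761974067
BEN,S2,V,P2,82.48461888758496,5.590922528937522,9.36487401002567,2.7990849059979803,6.916998665488432,287.60043316020983
BEN,S2,V,P3,67.92235247004717,5.431085706914679,9.089487182192256,3.645375181797568,6.733760862588019,352.41253515479417
BEN,S2,NV,P1,62.41555087112181,4.441811945216347,3.310564548886574,7.496794558034617,6.298817015425375,18.165960373704852
BEN,S2,NV,P2,71.00504807244589,3.96275735886114,4.7492074854131605,4.8672221522011805,2.719497103296521,0.0
BEN,S2,NV,P3,67.20851191944692,4.332841131082898,5.16107714691419,5.987598137321079,6.099175949400006,107.57238672449334
PAE,S1,V,P1,91.26406346613044,6.225905143864553,8.722722071969269,1.3106611681249456,10.698297675603902,378.88238072627297
PAE,S1,V,P2,64.16531479870854,5.183837854878869,10.412365440587593,2.8679298421459176,5.858523448438108,235.3116985345152
PAE,S1,V,P3,73.90160886375278,5.0929603293871155,10.102899759992189,2.839625162501606,7.8403106066962716,196.2826398009224
PAE,S1,NV,P1,70.97816702870136,5.3672148770637875,7.264312597762697,7.3258137683968965,2.562043863990761,117.31588200410827
PAE,S1,NV,P2,55.96568740961125,4.618899733308242,4.314027934148543,6.345362575021431,8.63487215624027,127.92238590346562
PAE,S1,NV,P3,65.34489955306381,4.402137535852688,5.679144406076943,5.041937419194248,5.852413756381552,54.085821039952506
PAE,S2,V,P1,84.07159651881503,4.294278677383888,9.846174978887934,5.996949816116714,7.315555426714555,328.0870210075068
PAE,S2,V,P2,71.75922691686696,5.56999794633303,9.778461741030956,4.899801610668183,9.250407270844248,256.75631409494457
PAE,S2,V,P3,79.05266830411935,5.266087836945806,8.800656425999993,3.3600818761844344,5.001798349821424,274.8747315462972
PAE,S2,NV,P1,58.95581678953112,5.12688320296967,4.937175872023948,6.284385792536421,5.684991840919321,0.0
PAE,S2,NV,P2,58.716174037384974,4.730598324951073,2.7476075304027914,7.084628174953472,6.094487262630924,69.70617725354482
PAE,S2,NV,P3,66.27753470638781,5.416222845232721,6.98404614866247,3.032315389413032,5.113601204798694,89.85992036500215
VIB,S1,V,P1,72.59451930443052,6.145381098823241,11.249466459140846,2.5572069414289818,6.459318125453173,285.0215558512535
VIB,S1,V,P2,68.64917680301834,5.327669552329612,10.727504596544945,3.7163840332301863,8.339527809948212,308.2498803654294
VIB,S1,V,P3,75.85599824107018,7.089629157233504,11.531416639205476,2.9548827747201387,9.291259994939569,254.07456313092598
VIB,S1,NV,P1,50.52581993504617,4.284892091483161,6.798764157062709,7.607611465976714,1.814406806746912,79.44925533364984
VIB,S1,NV,P2,57.83552775574877,5.986348006519913,7.7416778797210295,5.898835570840065,6.206236733025075,51.00955748790576
VIB,S1,NV,P3,63.003029249557734,4.87470582071345,6.777056123750772,5.788174916757401,5.1257492406493705,0.0
VIB,S2,V,P1,73.87312861755329,4.9626852836423065,8.9668828830053,4.581629727193549,8.790757754337756,265.9960563347347
VIB,S2,V,P2,65.14897447359827,5.951712933956673,7.743596334208893,3.454730793685729,4.812135026681815,268.9660988340076
VIB,S2,V,P3,68.3385262293473,5.825938692897011,9.626703403315322,4.50344510089281,8.969402695951121,327.9777682027616
VIB,S2,NV,P1,63.863760301600756,5.146763356252211,5.349747793171117,6.598469018560501,4.914839234431826,0.0
VIB,S2,NV,P2,64.89398630536877,5.522144558107297,5.571210853531924,5.290708740848585,6.932153910602932,0.0
VIB,S2,NV,P3,59.601993319550154,6.230373744724127,7.187602079468805,6.2112105768918395,6.458497112050101,0.0
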