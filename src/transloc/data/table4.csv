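id,linear_distance_3mo_km,n_fixes_linear_3mo,mcp_3mo_km2,n_fixes_3mo,mcp_6mo_km2,n_fixes_6mo,exploration_days,homerange_n_fixes,mcp100_km2,mcp50_km2,kde95_km2,kde50_km2,pct_reserve,pct_all_pa,centroid_dist_km,last_dist_km
Aju01,,,820.2,54,1316.0,103,93,92,1509.0,284.6,1196.3,108.6,39,54,13.5,24.2
Aju02,,,820.2,54,1316.0,103,93,92,1509.0,284.6,1196.3,108.6,39,54,13.5,17.0
Aju03,,,820.2,54,1316.0,103,93,92,1509.0,284.6,1196.3,108.6,39,54,13.5,24.7
Aju07,,,,,,,,,,,,,,,,3.9
Aju17,524.1,89,7905.2,89,8373.6,181,85,883,3209.1,253.9,931.7,203.1,0,89,147.1,159.4
Aju18,,,,,,,,,,,,,,,,38.3
Aju19,,,,,,,,,,,,,,,,10.9
Aju20,,,989.8,64,,,36,31,49.0,4.4,51.8,6.3,0,0,51.7,81.5
Aju26,590.5,91,11474.1,91,,,>112,,,,,,,,,281.0
Aju29,,,1068.5,46,1068.5,56,unknown,,,,,,,,,9.2
Aju30,577.6,92,7907.3,92,9048.9,141,>290,,,,,,,,,71.0
Aju34,,,,,,,unknown,,,,,,,,,24.4
Aju38,265.8,92,1179.9,92,3292.6,181,171,418,217.0,26.9,121.6,18.3,0,74,26.1,28.2
Aju40,,,,,,,,,,,,,,,,4.4
Aju41,147.1,90,138.9,90,1099.5,160,,,,,,,,,,78.0
Aju42,,,,,,,,,,,,,,,,31.9
Aju43,,,,,,,,,,,,,,,,31.9
Aju44,,,,,,,,,,,,,,,,31.9
Aju56,250.1,87,2465.0,87,13596.0,179,190,497,2624.8,94.6,929.5,81.5,0,0,118.1,140.6
Aju58,363.0,91,2520.1,91,4694.1,181,114,318,176.8,18.6,138.7,13.9,0,14,41.7,59.2
Aju59,,,,,,,,,,,,,,,,26.0
Aju65,582.6,91,1877.0,91,2015.0,165,13,275,1614.4,370.1,1182.2,193.2,0,0,64.7,71.1
Aju66,582.6,91,1877.0,91,2015.0,165,13,275,1614.4,370.1,1182.2,193.2,0,0,64.7,65.2
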