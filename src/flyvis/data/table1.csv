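species_id,H_width_mean,H_width_se,E_area_mean,E_area_se,OM_area_mean,OM_area_se,OM_number_mean,OM_number_se,delta_gamma_mean,delta_gamma_se,OC_diameter_mean,OC_diameter_se
Amobia signata,2297.6,109.0,887826.7,93027.5,341.2,21.9,2585.2,167.9,3.06,0.10,55.7,3.0
Apodacra seriemaculata,1494.0,68.4,395699.1,27351.6,273.7,14.0,1447.9,72.6,4.08,0.11,54.0,3.4
Craticulina tabaniformis,2394.1,76.5,615394.8,28390.5,413.3,18.5,1489.9,23.1,4.00,0.03,66.3,3.0
Eumacronychia persolla,2153.3,64.3,426282.4,11766.2,285.9,18.2,1502.6,68.2,3.99,0.09,61.8,10.0
Metopia argyrocephala,2012.0,34.4,441396.2,13343.4,282.8,14.0,1570.6,38.8,3.90,0.05,36.7,0.4
Miltogramma germari,2559.0,62.6,827724.4,27060.3,327.5,5.4,2527.5,71.0,3.07,0.04,72.7,2.6
Miltogramma punctata,2421.0,90.4,936436.3,75090.6,356.0,27.8,2635.3,82.2,3.01,0.05,78.0,2.6
Miltogramma turanica,2194.0,40.1,893903.0,31581.7,345.6,8.0,2589.9,87.6,3.04,0.05,61.0,1.6
Phrosinella fedtshenkoi,1984.6,35.2,397453.1,9953.1,270.0,9.3,1481.2,58.1,4.02,0.08,60.8,2.1
Phrosinella kocaki,2049.0,62.1,417403.2,22927.2,294.0,5.8,1416.9,62.9,4.12,0.09,67.8,2.8
Phylloteles pictipennis,1900.1,28.9,381743.4,14846.8,276.6,6.1,1381.8,53.3,4.17,0.08,43.3,1.2
Pterella melanura,1867.6,47.0,536610.9,24617.6,241.7,8.4,2219.5,56.5,3.28,0.04,64.1,1.1
Senotainia albifrons,2023.8,59.3,584752.0,30448.3,332.0,13.9,1761.9,62.1,3.69,0.06,71.6,6.6
Senotainia conica,1598.3,57.7,383844.8,28873.1,252.7,12.7,1510.5,60.9,3.99,0.09,66.1,3.1
Senotainia tricuspis,2464.8,47.6,642024.6,17713.1,300.3,5.2,2140.1,72.2,3.34,0.06,92.7,6.1
Sphenometopa claripennis,2020.7,65.3,457034.3,36559.1,299.1,9.5,1521.2,95.6,3.99,0.12,47.3,1.5
Taxigramma heteroneura,1357.8,76.1,252067.9,16010.4,224.7,7.8,1123.8,66.2,4.63,0.14,46.0,3.0
Taxigramma stictica,1614.4,32.3,306100.5,10115.5,239.1,7.4,1282.2,30.8,4.32,0.05,57.7,2.9
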