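species_id,F_length_mean,F_length_se,P_length_mean,P_length_se,A_length_mean,A_length_se,ANT_length_mean,ANT_length_se
Amobia signata,285.7,17.8,232.4,8.0,540.7,46.1,1058.8,60.5
Apodacra seriemaculata,464.9,34.7,173.0,6.0,180.1,27.7,818.0,54.6
Craticulina tabaniformis,498.9,24.5,240.6,5.0,358.6,23.0,1241.3,42.2
Eumacronychia persolla,418.8,70.5,255.3,8.7,1005.8,59.7,1679.7,128.5
Metopia argyrocephala,625.4,45.6,204.7,6.5,761.8,25.4,1571.5,68.3
Miltogramma germari,339.3,28.2,232.3,4.2,449.7,29.6,1021.3,44.3
Miltogramma punctata,326.9,23.6,221.9,5.0,404.4,10.2,953.1,33.2
Miltogramma turanica,330.9,13.6,211.9,7.3,363.4,11.2,901.8,20.1
Phrosinella fedtshenkoi,470.1,31.9,189.4,4.2,544.3,30.4,1203.8,52.7
Phrosinella kocaki,471.3,22.8,193.6,6.7,487.1,29.9,1152.0,42.0
Phylloteles pictipennis,378.6,7.9,188.6,4.2,571.4,28.0,1146.4,27.1
Pterella melanura,271.3,22.2,180.7,7.0,285.9,22.9,737.8,27.4
Senotainia albifrons,262.7,20.6,191.7,5.8,411.5,34.8,865.8,37.7
Senotainia conica,199.3,22.2,177.1,7.0,395.3,17.5,771.7,40.8
Senotainia tricuspis,335.5,24.2,222.0,2.7,576.0,31.5,1133.5,15.3
Sphenometopa claripennis,423.9,25.9,190.9,4.8,521.3,16.7,1127.7,21.7
Taxigramma heteroneura,242.0,15.5,175.5,6.8,452.3,31.0,870.2,46.0
Taxigramma stictica,284.3,7.2,187.6,4.3,542.3,31.8,1017.8,31.7
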