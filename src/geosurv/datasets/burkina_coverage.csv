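region_id,itn_use,malaria_treatment,exclusive_breastfeeding,breastfeeding_24h,postnatal_check_24h,measles_immunization,dpt3_immunization,all_antigen_immunization,vitamin_a,skilled_birth_attendance,antenatal_visits,family_planning,iptp,improved_sanitation,improved_water,itn_ownership
Boucle du Mouhoun,42.6,22.5,6.7,36.4,15.0,90.3,97.0,86.9,75.7,64.5,93.4,12.9,36.4,24.3,62.5,73.3
Cascades,49.8,19.2,10.1,45.6,18.1,90.5,79.2,71.7,49.2,77.5,95.5,16.5,43.8,33.2,89.6,81.5
Centre,33.1,36.1,2.4,55.3,15.2,96.8,93.7,88.0,59.8,96.4,98.7,32.2,32.3,76.9,94.6,72.7
Centre-Est,35.9,47.9,8.8,26.6,31.8,95.2,98.1,93.0,80.6,84.6,99.6,8.4,52.2,15.0,87.3,62.7
Centre-Nord,32.0,23.1,8.6,36.1,20.7,95.6,97.6,94.9,83.4,73.5,97.1,8.7,46.9,22.4,86.9,52.8
Centre-Ouest,46.6,36.8,6.8,29.7,19.5,85.9,91.6,82.8,41.2,60.7,95.2,8.8,47.2,16.8,65.0,74.0
Centre-Sud,38.2,45.7,7.3,45.4,27.7,94.9,96.2,92.4,89.2,86.4,99.3,16.8,51.3,11.1,83.7,62.8
Est,46.0,42.2,9.0,55.4,30.8,75.3,83.0,69.6,46.0,55.4,92.4,12.0,32.3,5.1,65.2,83.2
Hauts Bassins,36.2,42.0,7.3,38.6,4.5,88.5,87.8,81.1,64.1,73.1,96.0,28.3,29.6,27.5,76.4,63.3
Nord,65.7,42.0,6.0,46.8,21.5,91.7,93.6,88.8,72.4,61.4,94.8,9.0,40.0,25.7,64.3,98.1
Plateau Central,73.5,40.5,7.3,66.9,19.7,95.3,96.1,90.1,70.8,80.8,98.7,13.9,53.2,39.7,93.4,95.4
Sahel,37.3,20.1,5.2,35.4,5.4,79.2,82.0,74.0,36.5,40.1,88.3,7.8,19.9,9.2,61.6,81.5
Sud-Ouest,44.7,31.7,5.9,37.1,9.0,85.4,92.0,81.0,65.4,42.9,92.5,10.0,58.1,8.2,47.6,71.2
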