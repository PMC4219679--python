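item_id,label,icc,ci_low,ci_high
Q1,Are sidewalks present,1.00,1.00,1.00
Q2,Type of sidewalk present,0.92,0.89,0.95
Q3.concrete,Sidewalk surface: concrete,0.92,0.89,0.94
Q3.paving_bricks,Sidewalk surface: paving bricks,0.90,0.87,0.93
Q3.asphalt,Sidewalk surface: asphalt,0.81,0.75,0.87
Q4,Quality of sidewalk,0.90,0.86,0.93
Q5,Bicycle lanes present,1.00,1.00,1.00
Q6,Quality of bicycle lanes,0.95,0.93,0.97
Q7,Grass/dirt strip between sidewalk and road,0.90,0.86,0.93
Q8,Parking lots present,0.89,0.85,0.93
Q9,Width of street/road,0.88,0.83,0.92
Q10,Level of pedestrian density,0.93,0.90,0.95
Q11,Amount of obstacles seen,0.78,0.70,0.84
Q12,Level of motor vehicle density,0.89,0.84,0.92
Q13.bicycles,Number of bicycles seen,0.87,0.82,0.91
Q13.cars,Number of cars seen,0.92,0.89,0.95
Q13.buses,Number of buses seen,0.39,0.25,0.52
Q13.rickshaws,Number of rickshaws seen,0.85,0.79,0.89
Q13.motorcycles,Number of motorcycles/scooters seen,0.67,0.56,0.76
Q13.trucks,Number of trucks seen,0.85,0.80,0.90
Q14,Amount of parked cars seen,0.90,0.86,0.93
Q15,Are there crosswalks present,0.90,0.85,0.93
Q16,Number of crosswalks present,0.87,0.82,0.91
Q17a,Crosswalk: white/coloured painted lines,0.89,0.85,0.92
Q17b,Crosswalk: different road surface or paving,0.89,0.85,0.92
Q17c,Crosswalk: traffic signals,0.75,0.53,0.86
Q17d,Crosswalk: stop/yield signs,0.79,0.71,0.85
Q17e,Crosswalk: pedestrian activated signal,0.94,0.91,0.96
Q17f,Crosswalk: pedestrian crossing signs,0.85,0.79,0.89
Q18,Median strip quality,0.95,0.93,0.96
Q19.open_field,Natural feature: open field,0.76,0.67,0.82
Q19.water,Natural feature: bodies of water,0.75,0.66,0.82
Q19.mountains,Natural feature: mountains/hills,0.74,0.65,0.81
Q19.greenbelt,Natural feature: greenbelt/forest,0.30,0.12,0.47
Q19.desert,Natural feature: desert,,,
Q20,Percentage of natural features present,0.95,0.93,0.97
Q21,Number of trees planted,0.75,0.65,0.82
Q22,Number of man-made landscapes present,0.85,0.79,0.90
Q23,Graffiti present,0.60,0.48,0.70
Q24,Litter/garbage present,0.84,0.78,0.89
Q25.bench,Street furniture: benches,0.84,0.78,0.89
Q25.trashcan,Street furniture: trash can,0.86,0.80,0.90
Q25.newspaper_box,Street furniture: newspaper boxes,0.79,0.72,0.85
Q25.bike_rack,Street furniture: bike rack,0.83,0.77,0.88
Q25.parking_meter,Street furniture: parking meter,0.74,0.66,0.82
Q25.street_lamp,Street furniture: street lamp,0.87,0.82,0.91
Q25.bus_shelter,Street furniture: bus shelter,0.83,0.76,0.88
Q25.phone_booth,Street furniture: phone booth,0.72,0.63,0.80
Q26,Number of public art displayed,0.81,0.73,0.86
Q27,Are buildings or houses present,1.00,1.00,1.00
Q28,Number of buildings present,0.86,0.80,0.90
Q29,Amount of awnings present,0.86,0.81,0.90
Q30,Number of derelict or vacant buildings present,0.85,0.80,0.90
Q31,Exterior of buildings maintained,0.78,0.70,0.84
Q32,Diversity of building design/architecture,0.66,0.55,0.75
Q33,Opinion: safe and pedestrian friendly,0.72,0.62,0.80
Q34,Opinion: suitable for walking,0.74,0.65,0.81
Q35,Opinion: suitable for biking,0.27,0.14,0.41
Q36,Opinion: attractive buildings,0.63,0.52,0.72
Q37,Opinion: aesthetically appealing,0.74,0.65,0.82
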