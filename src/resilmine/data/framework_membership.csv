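no,indicator,dimension,CRI,PEOPLES,Sendai,Novel
1,Emergency medical facilities,Medical,1,1,1,0
2,Telemedicine infrastructure,Medical,0,0,0,1
3,Community health surveillance systems,Medical,0,0,1,1
4,Contact tracing capabilities,Medical,0,0,0,1
5,Isolation facility capacity,Medical,1,0,1,0
6,Personal protective equipment stockpiles,Medical,0,1,1,0
7,Emergency mental health support,Medical,0,0,0,1
8,Distributed medical resource networks,Medical,0,0,0,1
9,Community health worker capacity,Medical,1,1,0,0
10,Public health emergency protocols,Medical,1,1,1,0
11,Flexible space utilization capacity,Spatial,0,0,0,1
12,Digital infrastructure for remote activities,Spatial,0,0,0,1
13,Multi-functional public facilities,Spatial,1,0,0,1
14,Physical distancing-compatible design,Spatial,0,0,0,1
15,Ventilation systems in public spaces,Spatial,0,0,0,1
16,Transportation infrastructure resilience,Spatial,1,1,1,0
17,Emergency supply distribution networks,Spatial,1,0,1,0
18,Water and sanitation infrastructure,Spatial,1,1,1,0
19,Energy system redundancy,Spatial,1,0,1,0
20,Communication network reliability,Spatial,1,1,1,0
21,Social cohesion and mutual aid networks,Community,1,1,0,0
22,Vulnerable population support systems,Community,1,1,1,0
23,Community engagement mechanisms,Community,1,1,0,0
24,Risk communication channels,Community,1,1,1,0
25,Digital literacy and access,Community,0,0,0,1
26,Food security systems,Community,1,1,1,0
27,Economic support mechanisms,Community,1,1,0,0
28,Community leadership capacity,Community,1,1,0,0
29,Educational continuity systems,Community,0,0,0,1
30,Cultural adaptation strategies,Community,0,1,0,1
31,Green space accessibility during restrictions,Landscape,0,0,0,1
32,Outdoor recreation infrastructure,Landscape,1,0,0,1
33,Urban greenery for air quality,Landscape,0,1,0,1
34,Natural hazard mitigation,Landscape,1,1,1,0
35,Biodiversity and ecosystem health,Landscape,0,1,0,0
36,Climate adaptation measures,Landscape,1,1,1,0
37,Waste management systems,Landscape,1,1,1,0
38,Environmental monitoring capacity,Landscape,0,1,1,0
39,One Health integration,Landscape,0,0,0,1
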