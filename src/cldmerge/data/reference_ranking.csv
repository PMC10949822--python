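rank,variable,prominence,relation,frequency
1,Mental health,4.44,-2.47,10
2,Social connection & support,3.5,-1.09,12
3,Access to services and resources,2.6,0.19,10
4,Sport and recreation,2.54,0,12
5,Financial security,1.99,0.97,10
6,Education and training,1.99,0.09,11
7,School attendance,1.98,-0.18,8
8,Work & employment opportunities,1.75,-0.25,9
9,Access to transport,1.65,1.18,9
10,Physical activity,1.6,-0.26,6
11,Healthy role modelling,1.57,0.54,8
12,Supportive family environment,1.53,0.22,9
13,Healthy food consumption,1.48,-0.75,7
14,Physical health and fitness,1.44,-1.04,4
15,Family violence,1.42,0.25,5
16,Social media,1.41,0.8,8
17,Bullying,1.35,0.06,6
18,Access to housing,1.28,0.18,11
19,Social isolation,1.2,-0.47,3
20,Activities and events,1.18,-0.06,9
21,Safe and inclusive environments,1.15,-0.06,5
22,Alcohol and other substance use,1.09,-0.39,5
23,Sleep,1.02,-0.18,6
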