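patient_id,age,pregnant,trimester,tumor_location,tumor_size_cm,stage,procedures,systemic_treatments,vital_status
1,41,True,1,R,,3b,,5-FU;oxaliplatin,A
2,35,True,1,R,4.2,3,,,A
3,33,True,3,R,8,4b,,5-FU;oxaliplatin,D
4,22,True,delivery,CR,3.2,4a,,,A
5,41,True,,CL,,4a,,biologics;5-FU;oxaliplatin;panitumumab,D
6,28,False,,CL,8,4,hemicolectomy,5-FU;oxaliplatin,A
7,40,False,,CL,2.5,3,partial colectomy,5-FU;oxaliplatin;irinotecan,A
8,35,False,,R,2.4,1,low anterior resection,5-FU;oxaliplatin,A
9,36,False,,CL,2.4,3,hemicolectomy;right hepatectomy,5-FU,A
10,30,False,,CL,,3,partial colectomy;left hepatectomy,5-FU;oxaliplatin;irinotecan,A
11,42,False,,CL,3,3,partial colectomy;exploratory laparotomy;small intestine resection,5-FU;oxaliplatin;bevacizumab,A
12,,False,,CL,,4,,5-FU;oxaliplatin;irinotecan,A
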