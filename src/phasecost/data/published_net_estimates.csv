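treatment_type,phase,matched_net_usd,fe_net_usd,n_initial,n_continuing,n_terminal
Surgical resection only,initial,5555,5889,3552,3328,724
Surgical resection only,continuing,83,17,3552,3328,724
Surgical resection only,terminal,1484,4744,3552,3328,724
Surgical resection + LRT,initial,4740,5244,49,47,12
Surgical resection + LRT,continuing,330,545,49,47,12
Surgical resection + LRT,terminal,3570,4786,49,47,12
Surgical resection + TACE/TAE,initial,5251,5343,208,202,88
Surgical resection + TACE/TAE,continuing,785,413,208,202,88
Surgical resection + TACE/TAE,terminal,1447,4361,208,202,88
Surgical resection + others,initial,6182,6436,511,487,478
Surgical resection + others,continuing,629,546,511,487,478
Surgical resection + others,terminal,1806,4761,511,487,478
LRT only,initial,1330,1601,2044,1895,652
LRT only,continuing,407,237,2044,1895,652
LRT only,terminal,-448,2311,2044,1895,652
LRT + TACE/TAE,initial,2719,2881,720,688,250
LRT + TACE/TAE,continuing,594,310,720,688,250
LRT + TACE/TAE,terminal,-247,2244,720,688,250
LRT + chemotherapy,initial,2665,2982,240,226,221
LRT + chemotherapy,continuing,186,308,240,226,221
LRT + chemotherapy,terminal,-504,2076,240,226,221
LRT + others,initial,2656,2763,142,132,215
LRT + others,continuing,1559,1357,142,132,215
LRT + others,terminal,332,3317,142,132,215
TACE only,initial,2406,2658,2264,1932,1960
TACE only,continuing,498,274,2264,1932,1960
TACE only,terminal,-130,2689,2264,1932,1960
TACE + chemotherapy,initial,2098,2897,248,235,421
TACE + chemotherapy,continuing,976,1113,248,235,421
TACE + chemotherapy,terminal,-30,2898,248,235,421
TACE + chemotherapy + sorafenib,initial,2607,2854,90,86,169
TACE + chemotherapy + sorafenib,continuing,2452,2040,90,86,169
TACE + chemotherapy + sorafenib,terminal,45,3245,90,86,169
TAE only,initial,3055,4016,78,61,290
TAE only,continuing,-152,-75,78,61,290
TAE only,terminal,1747,4476,78,61,290
TAE + chemotherapy,initial,2791,3769,36,32,137
TAE + chemotherapy,continuing,83,685,36,32,137
TAE + chemotherapy,terminal,698,3051,36,32,137
Sorafenib only,initial,2958,2617,191,157,797
Sorafenib only,continuing,740,775,191,157,797
Sorafenib only,terminal,82,3113,191,157,797
Sorafenib + chemotherapy,initial,2631,2860,274,237,812
Sorafenib + chemotherapy,continuing,950,1036,274,237,812
Sorafenib + chemotherapy,terminal,410,3125,274,237,812
Others,initial,2863,3270,4276,3893,8742
Others,continuing,209,338,4276,3893,8742
Others,terminal,124,2870,4276,3893,8742
Total,initial,3353,3684,14923,13638,15968
Total,continuing,305,285,14923,13638,15968
Total,terminal,208,3026,14923,13638,15968
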