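region,n_institutions,registered_residents,health_professionals,nephsp_revenue,revenue_share_pct,nephsp_expenditure,expenditure_share_pct,operational_cost,equivalents_all,equivalents_nephsp
Eastern,10,586297,632,39531791.00,16.35,37626954.63,19.81,189910629.23,9918708.96,3910164.47
Southern,10,364804,439,14657212.10,19.44,16095246.19,21.63,74407942.38,8596446.46,2931318.24
Western,10,180562,328,11897644.58,14.21,12233751.26,17.83,68632173.76,3130390.91,1121255.62
Northern,10,301082,350,13589591.18,14.84,18494088.76,26.42,69995025.99,2535840.92,1285664.27
Central,10,262360,450,18263336.54,17.87,17843242.01,19.85,89872983.57,3200685.28,1200534.55
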