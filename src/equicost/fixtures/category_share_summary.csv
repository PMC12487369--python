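label,n,mean,sd
health education,5,26.52,8.90
elderly health management,5,26.35,3.91
establishment of resident health records,5,25.49,4.98
preventive inoculation,5,6.20,4.18
chronic disease management (hypertension),5,6.05,2.37
traditional Chinese medicine health management,5,2.99,0.54
children health management,5,2.76,1.61
chronic disease management (type 2 diabetes),5,1.44,0.66
maternal health management,5,1.30,0.23
severe mental disorder management,5,0.35,0.05
supervision and co-management of health and family planning,5,0.32,0.18
tuberculosis patient management,5,0.13,0.08
reporting and management of infectious diseases and public health emergencies,5,0.10,0.06
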