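group,sample_id,sensor_mean_umolL,sensor_sd_umolL,gcms_mean_umolL,gcms_sd_umolL,n_determinations,t_printed,relative_error_printed_percent
control_nonsmoker,1,2.5,0.11,2.6,0.082,5,1.30,-3.8
control_nonsmoker,2,1.7,0.063,1.8,0.050,5,2.50,-5.6
control_nonsmoker,3,1.3,0.067,1.2,0.031,5,1.82,8.3
control_nonsmoker,4,2.6,0.12,2.5,0.088,5,2.25,4.0
control_nonsmoker,5,2.1,0.11,2.2,0.017,5,1.61,-4.5
control_smoker,1,6.3,0.32,6.0,0.22,5,1.73,5.0
control_smoker,2,7.1,0.34,6.7,0.24,5,2.15,6.0
control_smoker,3,5.8,0.30,6.1,0.26,5,1.69,-4.9
control_smoker,4,6.5,0.23,6.3,0.25,5,1.32,3.2
control_smoker,5,7.3,0.30,7.7,0.34,5,1.97,-5.2
firemen_nonsmoker,1,3.4,0.16,3.6,0.12,5,2.16,-5.6
firemen_nonsmoker,2,2.9,0.13,3.1,0.12,5,2.53,-6.4
firemen_nonsmoker,3,3.8,0.20,3.6,0.15,5,1.79,5.6
firemen_nonsmoker,4,3.6,0.17,3.4,0.11,5,2.21,5.9
firemen_nonsmoker,5,3.4,0.18,3.5,0.15,5,0.95,-2.8
firemen_smoker,1,7.8,0.33,8.2,0.31,5,1.98,-4.9
firemen_smoker,2,9.6,0.45,9.1,0.37,5,1.92,5.5
firemen_smoker,3,8.5,0.41,8.0,0.28,5,2.25,6.2
firemen_smoker,4,10.2,0.49,9.8,0.33,5,1.51,-4.1
firemen_smoker,5,8.7,0.35,8.3,0.26,5,2.05,4.8
nonfatal_casualties,1,22.4,1.01,21.2,0.67,5,2.21,5.7
nonfatal_casualties,2,30.2,1.05,28.4,1.03,5,2.73,6.3
nonfatal_casualties,3,34.0,1.53,35.7,1.31,5,1.88,-4.8
nonfatal_casualties,4,19.5,1.03,20.8,0.88,5,2.14,-6.2
nonfatal_casualties,5,27.1,1.28,28.6,0.82,5,2.21,-5.2
fatal_casualties,1,42.6,2.24,45.0,1.64,5,1.93,-5.3
fatal_casualties,2,69.4,3.28,65.7,2.15,5,2.11,5.6
fatal_casualties,3,49.1,1.99,52.2,1.50,5,2.78,-5.9
fatal_casualties,4,55.0,2.84,51.7,1.63,5,2.25,6.4
fatal_casualties,5,62.1,2.70,59.5,1.82,5,1.78,4.4
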