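n_gs,n_peptide_bonds,tau_c_sim_ns,tau_c_exp_ns,tau_c_exp_err_ns,tau_o_sim_ns,tau_o_exp_ns,tau_o_exp_err_ns
2,4,12.5,14.6,4.5,26.0,36.7,12.5
3,6,17.6,17.6,1.5,31.5,41.7,7.5
5,10,24.7,20.5,2.1,53.1,48.5,4.7
7,14,27.7,32.7,4.5,52.8,54.3,4.9
9,18,58.1,48.9,7.5,81.2,56.5,6.0
12,24,,68.4,6.9,,73.0,7.1
15,30,,102.9,16.5,,80.6,10.5
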