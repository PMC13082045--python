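name,f_max_generic,l_opt,l_slack,pennation,v_max,tau_act,tau_deact,r_hip,r_knee,r_ankle
iliopsoas,1500.0,0.100,0.160,0.14,10.0,0.015,0.060,0.050,0.0,0.0
glut_max,1950.0,0.140,0.125,0.09,10.0,0.015,0.060,-0.062,0.0,0.0
rect_fem,1200.0,0.075,0.310,0.09,10.0,0.015,0.060,0.040,0.045,0.0
hamstrings,2600.0,0.080,0.330,0.17,10.0,0.015,0.060,-0.060,-0.030,0.0
vasti,5000.0,0.080,0.130,0.09,10.0,0.015,0.060,0.0,0.042,0.0
bifemsh,800.0,0.110,0.100,0.26,10.0,0.015,0.060,0.0,-0.030,0.0
gastroc,3100.0,0.055,0.400,0.21,10.0,0.015,0.060,0.0,-0.020,-0.050
soleus,3550.0,0.050,0.250,0.44,10.0,0.015,0.060,0.0,0.0,-0.048
tib_ant,1800.0,0.098,0.220,0.09,10.0,0.015,0.060,0.0,0.0,0.040
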