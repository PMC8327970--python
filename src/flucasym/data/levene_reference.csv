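model,F,df_between,p
FA10~Tooth,1.78,8,0.14
FA10~Class,0.19,1,0.67
FA10~Arcade,0.26,1,0.61
FA10~Metric,8.48,1,0.01
FA10~Sex,10.602,1,0.003
FA10:M1~Tooth Type,1.670,1,0.207
FA10:M1~Tooth Type*Sex,6.696,3,0.002
FA10:M3~Tooth Type,0.064,1,0.802
FA10:M3~Tooth Type*Sex,4.313,3,0.013
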