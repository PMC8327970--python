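sex,metric,tooth,fa10a,n
Female,Breadth,MNM1,0.01,20
Female,Breadth,MNM2,0.01,16
Female,Breadth,MNM3,0.01,20
Female,Breadth,MNP4,0.00,14
Female,Breadth,MXM1,0.01,31
Female,Breadth,MXM2,0.01,30
Female,Breadth,MXM3,0.03,34
Female,Breadth,MXP3,0.04,26
Female,Breadth,MXP4,0.01,31
Female,Length,MNM3,0.04,20
Female,Length,MNP4,0.06,15
Female,Length,MXM1,0.02,31
Female,Length,MXM2,0.04,32
Female,Length,MXM3,0.03,32
Female,Length,MXP3,0.04,27
Female,Length,MXP4,0.05,31
Male,Breadth,MNM1,0.01,17
Male,Breadth,MNM2,0.03,16
Male,Breadth,MNM3,0.01,14
Male,Breadth,MNP4,0.01,15
Male,Breadth,MXM1,0.01,31
Male,Breadth,MXM2,0.02,34
Male,Breadth,MXM3,0.02,34
Male,Breadth,MXP3,0.03,25
Male,Breadth,MXP4,0.02,29
Male,Length,MNM3,0.08,14
Male,Length,MNP4,0.07,15
Male,Length,MXM1,0.05,33
Male,Length,MXM2,0.07,35
Male,Length,MXM3,0.08,33
Male,Length,MXP4,0.10,29
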