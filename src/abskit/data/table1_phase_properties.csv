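system_id,abs_composition,volume_ratio,ph_il_rich,w_water_il_rich,w_il_il_rich,w_non_il_rich,ph_non_il_rich,w_water_non_il_rich,w_il_non_il_rich,w_non_non_il_rich
BP#1,30% [C2C1Im][CF3SO3] + 10% K3PO4,0.60,13.44,40.8785,56.5614,2.0652,13.18,73.4861,8.7068,16.8167
BP#2,30% [C4C1Im][CF3SO3] + 5% K3PO4,0.40,12.87,34.7684,64.4549,0.8176,13.25,78.6973,14.3401,6.7798
BP#3,30% [C2C1Im][C4F9SO3] + 2% K3PO4,0.94,12.78,43.6779,54.0350,0.3349,12.70,88.5482,4.2344,6.7525
BP#4,30% [C4C1Im][CF3SO3] + 25% sucrose,0.39,5.00,31.1747,57.6533,10.3701,5.25,47.1635,17.7208,32.0208
BP#5,30% [C2C1Im][C4F9SO3] + 25% sucrose,0.33,6.75,27.6055,66.8372,6.2338,6.75,53.5971,15.5558,31.8248
BP#6,30% [C4C1Im][CF3SO3] + 25% glucose,0.42,5.25,24.8533,72.0629,4.7980,5.25,53.2700,11.9669,32.7273
BP#7,30% [C2C1Im][C4F9SO3] + 25% glucose,0.43,6.50,20.5454,76.1935,4.1664,6.50,58.9178,7.7100,34.4053
BP#8,30% [C2C1Im][C4F9SO3] + 6% [N1112(OH)][H2PO4],0.89,3.37,41.3607,55.5876,1.5481,3.41,84.2108,4.0618,12.1251
BP#9,30% [C2C1Im][C4F9SO3] + 10% [N1112(OH)][H2PO4],0.59,3.65,17.7743,83.7801,0.6989,3.56,67.3516,5.1015,28.3455
BP#10,30% [C2C1Im][C4F9SO3] + 20% [N1112(OH)][H2PO4],0.42,3.99,30.1971,69.0974,1.0569,4.03,83.6562,2.3820,15.7034
BP#11,30% [C4C1Im][CF3SO3] + 20% [N1112(OH)][H2PO4],0.25,3.87,27.6891,66.5303,5.7394,3.78,54.8263,21.0133,23.5764
BP#12,30% [N1112(OH)][C4F9SO3] + 30% [N1112(OH)][H2PO4],0.60,4.15,25.3343,63.9061,10.1689,4.16,45.8046,7.6946,43.9659
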