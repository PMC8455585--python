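compound,set,pic50,comfa_pred,comfa_residual,comsia_pred,comsia_residual
Indoline11A,train,7.6,7.26,0.34,7.196,0.4
Indoline11B,train,7.53,7.651,-0.12,7.501,0.03
Indoline12,train,8.23,8.211,0.02,8.436,-0.21
Indoline13,train,7.03,7.027,0,7.07,-0.04
Indoline14,train,6.6,6.506,0.09,6.653,-0.05
Indoline14B,train,6.46,6.381,0.08,6.561,-0.1
Indoline24A,train,3.1,3.331,-0.23,2.876,0.22
Indoline24C,train,4.06,3.644,0.42,3.826,0.23
Indoline24D,train,3.68,3.792,-0.11,3.778,-0.1
Indoline24G,train,3.6,4.164,-0.56,4.091,-0.49
Indoline24H,train,3.99,4.115,-0.12,4.102,-0.11
Indoline24I,train,4.49,4.463,0.03,4.574,-0.08
Indoline25A,train,4.97,4.816,0.15,4.858,0.11
Indoline31A,train,6.89,6.874,0.02,6.824,0.07
Indoline31B,train,7.99,8.163,-0.17,8.185,-0.19
Indoline31C,train,7.48,7.668,-0.19,7.695,-0.22
Indoline31D,train,7.2,6.987,0.21,7.037,0.16
Indoline31F,train,6.46,6.171,0.29,6.265,0.2
Indoline31G,train,6.79,7.045,-0.25,7.05,-0.26
Indoline31H,train,7.59,7.533,0.06,7.137,0.45
Indoline32,train,8.35,8.407,-0.06,8.393,-0.04
Indoline33,train,7.15,7.184,-0.03,7.141,0.01
Indoline34,train,7.04,7.045,-0.01,7.095,-0.06
Acyl-32C,train,8.19,8.215,-0.03,8.139,0.05
Acyl-32F,train,7.39,7.487,-0.1,7.623,-0.23
Acyl-32G,train,7.82,7.647,0.17,7.826,-0.01
Acyl-32H,train,7.74,7.513,0.23,7.673,0.07
Acyl-32I,train,7.53,7.336,0.19,7.463,0.07
Acyl-32J,train,6.8,6.665,0.13,6.974,-0.17
Acyl-35,train,7.26,7.365,-0.11,7.424,-0.16
Acyl-38,train,8.74,8.769,-0.03,8.781,-0.04
Acyl-39,train,8.92,8.991,-0.07,8.808,0.11
Acyl-40,train,8.82,8.798,0.02,8.757,0.06
Acyl-41,train,8.52,8.614,-0.09,8.427,0.09
Acyl-42,train,8.64,8.78,-0.14,8.724,-0.08
Acyl-44,train,8.52,8.528,-0.01,8.385,0.14
Acyl-45,train,8.82,8.866,-0.05,8.836,-0.02
Acyl-48,train,7.51,7.454,0.06,7.447,0.06
Acyl-49,train,7.74,7.572,0.17,7.833,-0.09
Acyl-51,train,7.79,7.86,-0.07,7.638,0.15
Acyl-52,train,7.98,8.052,-0.07,7.895,0.09
Acyl-53,train,8.12,8.129,-0.01,8.065,0.05
Acyl-54,train,9.4,9.45,-0.05,9.467,-0.07
Indoline31E,test,7.27,7.228,0.04,6.304,0.97
Indoline31I,test,7.53,7.413,0.12,6.554,0.98
Indoline35,test,8.54,8.358,0.18,7.953,0.59
Indoline36,test,7.13,7.208,-0.08,7.864,-0.73
Acyl-32A,test,7.83,7.902,-0.07,7.997,-0.17
Acyl-32B,test,8.28,7.65,0.63,7.944,0.34
Acyl-32D,test,8.11,8.366,-0.26,7.934,0.18
Acyl-32E,test,8.19,7.616,0.57,7.915,0.27
Acyl-34,test,8.72,8.412,0.31,8.741,-0.02
Acyl-47,test,6.66,6.907,-0.25,5.896,0.76
Acyl-50,test,7.77,7.456,0.31,6.5,1.27
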