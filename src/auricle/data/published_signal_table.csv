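generic_name,brand_name,a,ror,ror_ci_low,ror_ci_high,prr,prr_ci_low,prr_ci_high,chi2
primidone,Mysoline,4,397.05,147.21,1070.9,388.71,145.89,1035.7,1541.44
valproic acid,Depakene,122,239.46,123.75,463.37,236.42,123.82,451.43,2093.08
methimazole,Tapazole,3,198.35,63.49,619.67,196.25,62.97,611.67,581.23
nevirapine,Viramune,15,138.24,82.9,230.51,137.23,82.44,228.44,2001.63
telbivudine,Sebivo,5,117.1,48.51,282.67,116.37,48.17,281.12,569.39
abacavir sulfate + lamivudine,Epzicom,4,107.18,40.04,286.89,106.57,40,283.95,416.85
allopurinol,Zyloprim,17,84.25,49.68,142.89,83.88,49.41,142.39,1132.28
isotretinoin,Accutane,37,63.06,23.59,168.6,62.85,23.59,167.46,242.62
carbamazepine,Tegretol,21,57.6,35.13,94.42,57.42,35.18,93.73,874.49
mycophenolate mofetil,CellCept,105,55.48,42.09,73.13,55.33,42.05,72.82,694.59
lamotrigine,Lamictal,66,50.69,36.02,71.35,50.56,36.23,70.55,1602.01
misoprostol,Cytotec,4,49.56,18.54,132.46,49.43,18.55,131.7,189.14
ondansetron,Zofran,15,43.84,26.32,73.01,43.74,26.28,72.81,618.1
ritonavir,Norvir,10,42.88,22.99,79.97,42.78,22.85,80.1,404.46
lamivudine + zidovudine,Combivir,6,37.12,16.63,82.87,37.05,16.59,82.75,209.35
lopinavir + ritonavir,Kaletra,14,35.32,20.84,59.86,35.25,20.76,59.84,460.16
fluconazole,Diflucan,6,32.32,14.48,72.15,32.27,14.45,72.08,180.82
nevirapine,Viramune,6,32.1,14.38,71.65,32.04,14.34,71.56,179.49
abacavir + lamivudine,Kivexa,3,30.83,9.92,95.82,30.78,9.88,95.93,86.2
topiramate,Topamax,20,30.52,16.37,56.91,30.47,16.27,57.05,282.54
mycophenolic acid,Myfortic,5,26.99,11.2,65.01,26.95,11.16,65.1,124.39
paroxetine,Paxil,19,24.17,9.05,64.55,24.14,9.06,64.3,288.42
fluoxetine,Prozac,25,23.69,12.71,44.17,23.66,12.64,44.3,215.1
lamivudine,Epivir,7,23.25,11.06,48.91,23.23,11.03,48.92,147.97
methotrexate,Trexall,49,22.51,16.54,30.65,22.49,16.44,30.77,830.34
emtricitabine + tenofovir disoproxil fumarate,Truvada,4,21.87,8.19,58.39,21.84,8.2,58.19,79.27
levocetirizine,Xyzal,3,19.02,6.12,59.1,19,6.1,59.22,51.03
naproxen,Aleve,7,18.35,6.87,49.01,18.34,6.88,48.87,65.33
levetiracetam,Keppra,29,17.78,11.55,27.39,17.77,11.55,27.35,326.15
dolutegravir,Tivicay,3,16.79,5.4,52.16,16.77,5.38,52.27,44.38
quetiapine,Seroquel,12,15.5,7.73,31.07,15.48,7.8,30.74,107.63
lacosamide,Vimpat,3,15.41,4.96,47.88,15.4,4.94,48,40.29
venlafaxine,Effexor,12,15.06,6.75,33.6,15.04,6.73,33.59,78.25
tacrolimus,Prograf,12,12.02,6.8,21.24,12.01,6.8,21.2,119.88
losartan,Cozaar,3,11.42,3.68,35.47,11.41,3.66,35.56,28.43
raltegravir,Isentress,4,11.36,4.26,30.33,11.36,4.26,30.27,37.64
imatinib,Gleevec,3,10.54,3.39,32.75,10.54,3.38,32.85,25.83
citalopram,Celexa,8,10.19,5.08,20.42,10.18,5.13,20.22,65.77
ramipril,Altace,3,9.86,3.17,30.63,9.86,3.16,30.73,23.81
diazepam,Valium,3,9.55,3.07,29.65,9.54,3.06,29.73,22.88
hydroxychloroquine,Plaquenil,5,9.09,3.77,21.88,9.08,3.76,21.93,35.8
escitalopram,Lexapro,3,8.75,2.82,27.17,8.74,2.8,27.24,20.52
letrozole,Femara,3,8.46,2.72,26.26,8.45,2.71,26.34,19.66
lisinopril,Prinivil,4,7.66,2.87,20.45,7.66,2.87,20.41,23.07
tacrolimus,Prograf,4,5.19,1.95,13.86,5.19,1.95,13.83,13.49
prednisone,Deltasone,3,5,1.61,15.54,5,1.6,15.58,9.59
cyclophosphamide,Cytoxan,3,4.94,1.59,15.35,4.94,1.58,15.4,9.4
gabapentin,Neurontin,6,3.56,1.6,7.94,3.56,1.59,7.95,10.98
metformin,Glucophage,5,2.58,1.07,6.2,2.58,1.07,6.23,4.8
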