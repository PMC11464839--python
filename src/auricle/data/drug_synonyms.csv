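raw_name,generic_name
mysoline,primidone
primidone,primidone
depakene,valproic acid
depakote,valproic acid
valproic acid,valproic acid
tapazole,methimazole
methimazole,methimazole
viramune,nevirapine
nevirapine,nevirapine
sebivo,telbivudine
telbivudine,telbivudine
epzicom,abacavir sulfate + lamivudine
abacavir sulfate + lamivudine,abacavir sulfate + lamivudine
zyloprim,allopurinol
allopurinol,allopurinol
accutane,isotretinoin
isotretinoin,isotretinoin
tegretol,carbamazepine
carbamazepine,carbamazepine
cellcept,mycophenolate mofetil
mycophenolate mofetil,mycophenolate mofetil
lamictal,lamotrigine
lamotrigine,lamotrigine
cytotec,misoprostol
misoprostol,misoprostol
zofran,ondansetron
ondansetron,ondansetron
norvir,ritonavir
ritonavir,ritonavir
combivir,lamivudine + zidovudine
lamivudine + zidovudine,lamivudine + zidovudine
kaletra,lopinavir + ritonavir
lopinavir + ritonavir,lopinavir + ritonavir
diflucan,fluconazole
fluconazole,fluconazole
kivexa,abacavir + lamivudine
abacavir + lamivudine,abacavir + lamivudine
topamax,topiramate
topiramate,topiramate
myfortic,mycophenolic acid
mycophenolic acid,mycophenolic acid
paxil,paroxetine
paroxetine,paroxetine
prozac,fluoxetine
fluoxetine,fluoxetine
epivir,lamivudine
lamivudine,lamivudine
trexall,methotrexate
methotrexate,methotrexate
truvada,emtricitabine + tenofovir disoproxil fumarate
emtricitabine + tenofovir disoproxil fumarate,emtricitabine + tenofovir disoproxil fumarate
xyzal,levocetirizine
levocetirizine,levocetirizine
aleve,naproxen
naproxen,naproxen
keppra,levetiracetam
levetiracetam,levetiracetam
tivicay,dolutegravir
dolutegravir,dolutegravir
seroquel,quetiapine
quetiapine,quetiapine
vimpat,lacosamide
lacosamide,lacosamide
effexor,venlafaxine
venlafaxine,venlafaxine
prograf,tacrolimus
tacrolimus,tacrolimus
cozaar,losartan
losartan,losartan
isentress,raltegravir
raltegravir,raltegravir
gleevec,imatinib
imatinib,imatinib
celexa,citalopram
citalopram,citalopram
altace,ramipril
ramipril,ramipril
valium,diazepam
diazepam,diazepam
plaquenil,hydroxychloroquine
hydroxychloroquine,hydroxychloroquine
lexapro,escitalopram
escitalopram,escitalopram
femara,letrozole
letrozole,letrozole
prinivil,lisinopril
lisinopril,lisinopril
deltasone,prednisone
prednisone,prednisone
cytoxan,cyclophosphamide
cyclophosphamide,cyclophosphamide
neurontin,gabapentin
gabapentin,gabapentin
glucophage,metformin
metformin,metformin
ibuprofen,ibuprofen
paracetamol,paracetamol
acetaminophen,paracetamol
tylenol,paracetamol
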