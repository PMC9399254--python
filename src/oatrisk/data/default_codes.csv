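code,system,category
T40,ICD10,nonfatal_overdose
T43,ICD10,nonfatal_overdose
T50.9,ICD10,nonfatal_overdose
X42,ICD10,nonfatal_overdose
X42,ICD10,fatal_overdose
X44,ICD10,fatal_overdose
Y12,ICD10,fatal_overdose
T40,ICD10,fatal_overdose
T43,ICD10,fatal_overdose
Z915,READ,overdose_history
TJ00,READ,overdose_history
U1,READ,self_harm_history
TK,READ,self_harm_history
BUP-PATCH-5,PRODUCT,analgesia_exclusion
BUP-PATCH-10,PRODUCT,analgesia_exclusion
MTD-LINCTUS,PRODUCT,analgesia_exclusion
BUP-SL-04MG,PRODUCT,analgesia_exclusion
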