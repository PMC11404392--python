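drug_code,drug_name,opioid_class,strength_mg_per_unit,mme_factor
MOR15,morphine sulfate 15 mg tablet,analgesic,15,1.0
MOR30,morphine sulfate 30 mg tablet,analgesic,30,1.0
OXY5,oxycodone 5 mg tablet,analgesic,5,1.5
OXY10,oxycodone 10 mg tablet,analgesic,10,1.5
HYDAPAP5,hydrocodone 5 mg-acetaminophen 325 mg tablet,combination,5,1.0
HYDAPAP10,hydrocodone 10 mg-acetaminophen 325 mg tablet,combination,10,1.0
CODAPAP30,codeine 30 mg-acetaminophen 300 mg tablet,combination,30,0.15
TRAM50,tramadol 50 mg tablet,analgesic,50,0.1
HMOR2,hydromorphone 2 mg tablet,analgesic,2,4.0
OXYM5,oxymorphone 5 mg tablet,analgesic,5,3.0
TAP50,tapentadol 50 mg tablet,analgesic,50,0.4
METH5,methadone 5 mg tablet,analgesic,5,4.0
GCOD2,guaifenesin-codeine 2 mg/mL syrup,antitussive,2,0.15
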