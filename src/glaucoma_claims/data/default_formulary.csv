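product_code,generic_name,drug_classes,is_fixed_combination,bottle_volume_ml,dosing_frequency,is_generic
LAT01,latanoprost,PG,false,2.5,ONCE_DAILY,false
LAT02,latanoprost,PG,false,2.5,ONCE_DAILY,true
TAF01,tafluprost,PG,false,2.5,ONCE_DAILY,false
TRA01,travoprost,PG,false,2.5,ONCE_DAILY,false
BIM01,bimatoprost,PG,false,2.5,ONCE_DAILY,false
TIM01,timolol,BB,false,5.0,MULTI_DAILY,false
TIM02,timolol,BB,false,5.0,MULTI_DAILY,true
CAR01,carteolol,BB,false,5.0,MULTI_DAILY,false
NIP01,nipradilol,ABB,false,5.0,MULTI_DAILY,false
BUN01,bunazosin,AB,false,5.0,MULTI_DAILY,false
DOR01,dorzolamide,CAI,false,5.0,MULTI_DAILY,false
BZM01,brinzolamide,CAI,false,5.0,MULTI_DAILY,false
BRI01,brimonidine,AA,false,5.0,MULTI_DAILY,false
PIL01,pilocarpine,MA,false,5.0,MULTI_DAILY,false
RIP01,ripasudil,ROCKI,false,5.0,MULTI_DAILY,false
DTFC01,dorzolamide/timolol,CAI|BB,true,5.0,MULTI_DAILY,false
DTFC02,dorzolamide/timolol,CAI|BB,true,5.0,MULTI_DAILY,true
BTFC01,brinzolamide/timolol,CAI|BB,true,5.0,MULTI_DAILY,false
LTFC01,latanoprost/timolol,PG|BB,true,2.5,ONCE_DAILY,false
LTFC02,latanoprost/timolol,PG|BB,true,2.5,ONCE_DAILY,true
TTFC01,travoprost/timolol,PG|BB,true,2.5,ONCE_DAILY,false
TAFC01,tafluprost/timolol,PG|BB,true,2.5,ONCE_DAILY,false
ABFC01,brimonidine/timolol,AA|BB,true,5.0,MULTI_DAILY,false
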