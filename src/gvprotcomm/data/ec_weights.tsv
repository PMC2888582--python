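evidence_code	weight
EXP	4
IDA	4
IPI	4
IMP	4
IGI	4
IEP	4
ISS	3
ISO	3
ISA	3
TAS	3
IC	3
NAS	2
IEA	1
ND	0
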