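# Default angle triplet table: angle name -> [first, vertex, last].
# Each of the 12 monitored angles is labelled by its vertex landmark.
# Elbow and knee follow the classic three-point convention
# (shoulder-elbow-wrist, hip-knee-ankle); shoulder and hip use the
# same-side torso chain; wrist and ankle, whose vertices have a single
# skeletal neighbour within the 12-point set, close against the
# same-side hip. Users may substitute their own table via
# Topology.from_yaml().
SHL: [HL, SHL, ELL]
SHR: [HR, SHR, ELR]
ELL: [SHL, ELL, WL]
ELR: [SHR, ELR, WR]
WL: [ELL, WL, HL]
WR: [ELR, WR, HR]
HL: [SHL, HL, KL]
HR: [SHR, HR, KR]
KL: [HL, KL, ANL]
KR: [HR, KR, ANR]
ANL: [KL, ANL, HL]
ANR: [KR, ANR, HR]
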