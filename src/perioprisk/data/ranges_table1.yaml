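# Normal value ranges of intraoperative monitoring attributes (closed intervals).
# Units are the conventional clinical ones per attribute (bpm, mmHg, breaths/min,
# mmHg end-tidal CO2, degrees C, percent saturation).
# MAP and MBP carry an upper bound of 10000, a sentinel meaning "no clinically
# enforced upper limit"; it is kept verbatim so the catalogue matches the
# published reference table bit-exactly.
HR: [50, 100]
SBP: [90, 140]
DBP: [60, 90]
CVP: [5, 12]
RR: [12, 20]
ETCO2: [35, 45]
T: [36.2, 37.2]
RT: [36.5, 37.7]
SpO2: [95, 100]
ADBP: [60, 90]
PULSE: [60, 100]
MAP: [60, 10000]
MBP: [60, 10000]
ASBP: [90, 140]
SPPA: [15, 30]
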