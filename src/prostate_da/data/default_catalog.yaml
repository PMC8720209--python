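# Default treatment catalog for the decision-aid engine.
#
# Eligibility follows NCCN-style convention for radiation-focused care by
# broad risk category; it is configuration, not code, and institutions
# should adapt it.
#
# Success probabilities are 5-year freedom from biochemical failure (FFBF).
# The values below are PLACEHOLDERS in a clinically plausible range; they
# are not published estimates and must be replaced with institutional or
# trial-derived numbers before clinical use.
treatments:          # least-intensive first; this order also breaks cost ties
  - active_surveillance
  - SBRT
  - EBRT_hypofractionated
  - EBRT_standard
  - EBRT_HDR
  - EBRT_ADT
  - EBRT_HDR_ADT
eligibility:
  LOW:
    - active_surveillance
    - SBRT
    - EBRT_hypofractionated
    - EBRT_standard
  INTERMEDIATE:
    - SBRT
    - EBRT_hypofractionated
    - EBRT_standard
    - EBRT_HDR
    - EBRT_ADT
  HIGH:
    - EBRT_ADT
    - EBRT_HDR_ADT
success:             # placeholder P(5-year FFBF) per treatment x broad risk
  active_surveillance:
    LOW: 0.90
  SBRT:
    LOW: 0.95
    INTERMEDIATE: 0.90
  EBRT_hypofractionated:
    LOW: 0.94
    INTERMEDIATE: 0.89
  EBRT_standard:
    LOW: 0.94
    INTERMEDIATE: 0.89
  EBRT_HDR:
    INTERMEDIATE: 0.92
  EBRT_ADT:
    INTERMEDIATE: 0.91
    HIGH: 0.84
  EBRT_HDR_ADT:
    HIGH: 0.88
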