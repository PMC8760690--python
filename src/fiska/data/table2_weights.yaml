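# Default allocation weight table.
# Three levels: criterion relative weight x sub-criterion relative weight
# (x bin relative weight where the sub-criterion is binned) = global weight.
# Global weights are stated explicitly because one published cell (4 HLA
# mismatches, 0.00947) differs from the exact product (0.00938) by 9e-5;
# the loader checks product consistency to +/- 2e-4.
criteria:
  equity:
    weight: 0.33
    sub_criteria:
      medical_urgency:
        weight: 0.54
        global: 0.1782
      pra_over_80:
        weight: 0.14
        global: 0.0462
      recipient_age:
        weight: 0.27
        bins:
          under_11: {weight: 0.54, global: 0.0481}
          age_11_15: {weight: 0.29, global: 0.0258}
          age_15_18: {weight: 0.16, global: 0.0143}
      waiting_time_per_year:
        weight: 0.05
        global: 0.0165
  utility:
    weight: 0.67
    sub_criteria:
      hla_mismatching:
        weight: 0.35
        bins:
          mm0: {weight: 0.56, global: 0.1313}
          mm1: {weight: 0.21, global: 0.0492}
          mm2: {weight: 0.11, global: 0.0258}
          mm3: {weight: 0.06, global: 0.0141}
          mm4: {weight: 0.04, global: 0.00947}
          mm5: {weight: 0.02, global: 0.0047}
      blood_type_matching:
        weight: 0.16
        bins:
          identical: {weight: 0.83, global: 0.0889}
          compatible: {weight: 0.17, global: 0.0182}
      age_difference:
        weight: 0.11
        bins:
          under_5: {weight: 0.69, global: 0.0509}
          diff_5_15: {weight: 0.24, global: 0.0177}
          over_15: {weight: 0.07, global: 0.0052}
      predicted_survival:
        weight: 0.38
        bins:
          under_1: {weight: 0.06, global: 0.0153}
          surv_1_5: {weight: 0.26, global: 0.0662}
          over_5: {weight: 0.68, global: 0.1731}
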