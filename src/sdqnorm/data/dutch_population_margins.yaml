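# Dutch adolescent population margins (Statistics Netherlands), used for
# post-stratification of the norm groups.
gender:
  male: 0.495
  female: 0.505
ethnic_background:
  majority: 0.786
  other: 0.214
maternal_education:
  low: 0.236
  medium: 0.417
  high: 0.347
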