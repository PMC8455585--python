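{
  "description": "Bookkeeping for the 57-compound acylureidoindoline series: which compounds formed the initial 45/12 train/test split and which three were later dropped as outliers. The published activity table lists only the 54 retained compounds; the three outliers are known by name. Their original partition membership is a package convention (two in training, one in test), chosen so that outlier removal yields the published 43-compound training set and 11-compound test set.",
  "test_ids": [
    "Indoline31E",
    "Indoline31I",
    "Indoline35",
    "Indoline36",
    "Acyl-32A",
    "Acyl-32B",
    "Acyl-32D",
    "Acyl-32E",
    "Acyl-34",
    "Acyl-47",
    "Acyl-50",
    "Indoline-25H"
  ],
  "outlier_ids": [
    "Acyl-43",
    "Indoline-24B",
    "Indoline-25H"
  ]
}
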