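{
 "organism": "S_glossinidius",
 "status": {
  "thiI": "functional",
  "thiF": "functional",
  "iscS": "functional",
  "thiS": "pseudogene",
  "dxs": "functional",
  "thiG": "pseudogene",
  "thiH": "pseudogene",
  "thiC": "pseudogene",
  "thiD": "absent",
  "thiE": "pseudogene",
  "ybjQ": "functional",
  "thiL": "functional",
  "thiM": "functional",
  "thiK": "functional",
  "tenA2": "functional",
  "thiP": "functional",
  "thiQ": "functional",
  "tbpA": "functional",
  "argA": "pseudogene",
  "argB": "functional",
  "argC": "pseudogene",
  "argD": "pseudogene",
  "argE": "functional",
  "argF": "functional",
  "argG": "pseudogene",
  "argH": "functional",
  "speA": "functional",
  "speB": "functional",
  "speC": "pseudogene",
  "lysC": "functional",
  "asd": "functional",
  "dapA": "functional",
  "dapB": "functional",
  "dapD": "functional",
  "dapE": "functional",
  "dapF": "functional",
  "lysA": "functional",
  "SG1602": "functional"
 }
}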