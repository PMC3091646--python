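{
 "organism": "W_glossinidia",
 "status": {
  "thiI": "absent",
  "thiF": "pseudogene",
  "iscS": "absent",
  "thiS": "functional",
  "dxs": "functional",
  "thiG": "functional",
  "thiH": "functional",
  "thiC": "functional",
  "thiD": "functional",
  "thiE": "functional",
  "ybjQ": "absent",
  "thiL": "functional",
  "thiM": "absent",
  "thiK": "absent",
  "tenA2": "absent",
  "thiP": "absent",
  "thiQ": "absent",
  "tbpA": "absent"
 }
}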