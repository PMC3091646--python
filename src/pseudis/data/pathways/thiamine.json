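{
 "name": "thiamine_biosynthesis",
 "external_inputs": [
  "pyruvate",
  "glyceraldehyde-3-phosphate",
  "L-cysteine",
  "L-tyrosine",
  "AIR",
  "THZ"
 ],
 "targets": [
  "thiamine-diphosphate",
  "THZ-P",
  "HMP-PP"
 ],
 "reactions": [
  {
   "id": "dxs",
   "substrates": [
    "pyruvate",
    "glyceraldehyde-3-phosphate"
   ],
   "products": [
    "DXP"
   ],
   "gene_requirement": "dxs"
  },
  {
   "id": "sulfur_relay",
   "substrates": [
    "L-cysteine"
   ],
   "products": [
    "ThiS-thiocarboxylate"
   ],
   "gene_requirement": [
    "AND",
    "iscS",
    "thiI",
    "thiF",
    "thiS"
   ]
  },
  {
   "id": "thiazole_synthase",
   "substrates": [
    "DXP",
    "ThiS-thiocarboxylate",
    "L-tyrosine"
   ],
   "products": [
    "THZ-P"
   ],
   "gene_requirement": [
    "AND",
    "thiG",
    "thiH"
   ]
  },
  {
   "id": "thiM",
   "substrates": [
    "THZ"
   ],
   "products": [
    "THZ-P"
   ],
   "gene_requirement": "thiM"
  },
  {
   "id": "tenA2",
   "substrates": [
    "thiamine"
   ],
   "products": [
    "THZ",
    "HMP"
   ],
   "gene_requirement": "tenA2"
  },
  {
   "id": "thiC",
   "substrates": [
    "AIR"
   ],
   "products": [
    "HMP-P"
   ],
   "gene_requirement": "thiC"
  },
  {
   "id": "thiD",
   "substrates": [
    "HMP-P"
   ],
   "products": [
    "HMP-PP"
   ],
   "gene_requirement": "thiD"
  },
  {
   "id": "hmp_salvage",
   "substrates": [
    "HMP"
   ],
   "products": [
    "HMP-PP"
   ],
   "gene_requirement": "thiD"
  },
  {
   "id": "thiamine_phosphate_synthase",
   "substrates": [
    "THZ-P",
    "HMP-PP"
   ],
   "products": [
    "TMP"
   ],
   "gene_requirement": [
    "OR",
    "thiE",
    "ybjQ"
   ]
  },
  {
   "id": "thiL",
   "substrates": [
    "TMP"
   ],
   "products": [
    "thiamine-diphosphate"
   ],
   "gene_requirement": "thiL"
  },
  {
   "id": "thiamine_transport",
   "substrates": [
    "thiamine_ext"
   ],
   "products": [
    "thiamine"
   ],
   "gene_requirement": [
    "AND",
    "thiP",
    "thiQ",
    "tbpA"
   ],
   "kind": "transport"
  },
  {
   "id": "thiK",
   "substrates": [
    "thiamine"
   ],
   "products": [
    "TMP"
   ],
   "gene_requirement": "thiK"
  }
 ]
}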