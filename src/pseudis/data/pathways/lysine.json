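{
 "name": "lysine_biosynthesis",
 "external_inputs": [
  "L-aspartate"
 ],
 "targets": [
  "L-lysine",
  "meso-diaminopimelate"
 ],
 "reactions": [
  {
   "id": "dap_early",
   "substrates": [
    "L-aspartate"
   ],
   "products": [
    "tetrahydrodipicolinate"
   ],
   "gene_requirement": [
    "AND",
    "lysC",
    "asd",
    "dapA",
    "dapB"
   ]
  },
  {
   "id": "dapD",
   "substrates": [
    "tetrahydrodipicolinate"
   ],
   "products": [
    "N-succinyl-2-amino-6-ketopimelate"
   ],
   "gene_requirement": "dapD"
  },
  {
   "id": "sdap_aminotransferase",
   "substrates": [
    "N-succinyl-2-amino-6-ketopimelate"
   ],
   "products": [
    "N-succinyl-diaminopimelate"
   ],
   "gene_requirement": [
    "OR",
    "argD",
    "SG1602"
   ]
  },
  {
   "id": "dapEF",
   "substrates": [
    "N-succinyl-diaminopimelate"
   ],
   "products": [
    "meso-diaminopimelate"
   ],
   "gene_requirement": [
    "AND",
    "dapE",
    "dapF"
   ]
  },
  {
   "id": "lysA",
   "substrates": [
    "meso-diaminopimelate"
   ],
   "products": [
    "L-lysine"
   ],
   "gene_requirement": "lysA"
  }
 ]
}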