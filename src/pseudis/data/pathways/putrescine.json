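{
 "name": "putrescine_biosynthesis",
 "external_inputs": [
  "L-arginine"
 ],
 "targets": [
  "putrescine"
 ],
 "reactions": [
  {
   "id": "speA",
   "substrates": [
    "L-arginine"
   ],
   "products": [
    "agmatine"
   ],
   "gene_requirement": "speA"
  },
  {
   "id": "speB",
   "substrates": [
    "agmatine"
   ],
   "products": [
    "putrescine",
    "urea"
   ],
   "gene_requirement": "speB"
  },
  {
   "id": "speC",
   "substrates": [
    "L-ornithine"
   ],
   "products": [
    "putrescine"
   ],
   "gene_requirement": "speC"
  }
 ]
}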