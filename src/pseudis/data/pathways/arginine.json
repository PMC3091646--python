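{
 "name": "arginine_biosynthesis",
 "external_inputs": [
  "L-glutamate",
  "carbamoyl-phosphate"
 ],
 "targets": [
  "L-arginine",
  "L-ornithine"
 ],
 "reactions": [
  {
   "id": "argA",
   "substrates": [
    "L-glutamate"
   ],
   "products": [
    "N-acetylglutamate"
   ],
   "gene_requirement": "argA"
  },
  {
   "id": "argB",
   "substrates": [
    "N-acetylglutamate"
   ],
   "products": [
    "N-acetylglutamyl-phosphate"
   ],
   "gene_requirement": "argB"
  },
  {
   "id": "argC",
   "substrates": [
    "N-acetylglutamyl-phosphate"
   ],
   "products": [
    "N-acetylglutamate-semialdehyde"
   ],
   "gene_requirement": "argC"
  },
  {
   "id": "argD",
   "substrates": [
    "N-acetylglutamate-semialdehyde"
   ],
   "products": [
    "N-acetylornithine"
   ],
   "gene_requirement": "argD"
  },
  {
   "id": "argE",
   "substrates": [
    "N-acetylornithine"
   ],
   "products": [
    "L-ornithine"
   ],
   "gene_requirement": "argE"
  },
  {
   "id": "argF",
   "substrates": [
    "L-ornithine",
    "carbamoyl-phosphate"
   ],
   "products": [
    "L-citrulline"
   ],
   "gene_requirement": "argF"
  },
  {
   "id": "argG",
   "substrates": [
    "L-citrulline"
   ],
   "products": [
    "argininosuccinate"
   ],
   "gene_requirement": "argG"
  },
  {
   "id": "argH",
   "substrates": [
    "argininosuccinate"
   ],
   "products": [
    "L-arginine"
   ],
   "gene_requirement": "argH"
  }
 ]
}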