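[
 {
  "name": "bacteria-C-cycle-synthetic-default",
  "cycle": "C",
  "community": "bacteria",
  "genes": {
   "bC01": "beta-glucosidase",
   "bC02": "endo-1,4-beta-xylanase",
   "bC03": "xylan 1,4-beta-xylosidase",
   "bC04": "cellobiohydrolase",
   "bC05": "formate dehydrogenase",
   "bC06": "malate dehydrogenase",
   "bC07": "pyruvate decarboxylase",
   "bC08": "peroxidase",
   "bC09": "polyphenol oxidase",
   "bC10": "alpha-amylase",
   "bC11": "glucoamylase",
   "bC12": "pectinesterase",
   "bC13": "chitinase",
   "bC14": "laccase",
   "bC15": "catalase",
   "bC16": "isocitrate dehydrogenase",
   "bC17": "citrate synthase",
   "bC18": "aconitate hydratase",
   "bC19": "fumarate hydratase"
  }
 },
 {
  "name": "bacteria-N-cycle-synthetic-default",
  "cycle": "N",
  "community": "bacteria",
  "genes": {
   "bN01": "urease",
   "bN02": "nitrate reductase",
   "bN03": "nitrite reductase",
   "bN04": "hydroxylamine reductase",
   "bN05": "nitrogenase",
   "bN06": "glutamine synthetase",
   "bN07": "glutamate dehydrogenase",
   "bN08": "ammonia monooxygenase",
   "bN09": "nitric oxide reductase",
   "bN10": "nitrous oxide reductase",
   "bN11": "asparaginase",
   "bN12": "arginase",
   "bN13": "amidase"
  }
 },
 {
  "name": "bacteria-P-cycle-synthetic-default",
  "cycle": "P",
  "community": "bacteria",
  "genes": {
   "bP01": "acid phosphatase",
   "bP02": "alkaline phosphatase",
   "bP03": "phytase",
   "bP04": "exopolyphosphatase",
   "bP05": "polyphosphate kinase",
   "bP06": "phosphonatase",
   "bP07": "C-P lyase",
   "bP08": "glycerophosphodiesterase",
   "bP09": "pyrophosphatase"
  }
 },
 {
  "name": "fungi-C-cycle-synthetic-default",
  "cycle": "C",
  "community": "fungi",
  "genes": {
   "fC01": "beta-glucosidase",
   "fC02": "endo-1,4-beta-xylanase",
   "fC03": "xylan 1,4-beta-xylosidase",
   "fC04": "cellobiohydrolase",
   "fC05": "formate dehydrogenase",
   "fC06": "malate dehydrogenase",
   "fC07": "pyruvate decarboxylase",
   "fC08": "peroxidase",
   "fC09": "polyphenol oxidase",
   "fC10": "alpha-amylase",
   "fC11": "glucoamylase",
   "fC12": "pectinesterase"
  }
 },
 {
  "name": "fungi-N-cycle-synthetic-default",
  "cycle": "N",
  "community": "fungi",
  "genes": {
   "fN01": "urease",
   "fN02": "nitrate reductase",
   "fN03": "nitrite reductase",
   "fN04": "hydroxylamine reductase",
   "fN05": "nitrogenase",
   "fN06": "glutamine synthetase"
  }
 },
 {
  "name": "fungi-P-cycle-synthetic-default",
  "cycle": "P",
  "community": "fungi",
  "genes": {
   "fP01": "acid phosphatase",
   "fP02": "alkaline phosphatase",
   "fP03": "phytase",
   "fP04": "exopolyphosphatase",
   "fP05": "polyphosphate kinase",
   "fP06": "phosphonatase",
   "fP07": "C-P lyase",
   "fP08": "glycerophosphodiesterase"
  }
 }
]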