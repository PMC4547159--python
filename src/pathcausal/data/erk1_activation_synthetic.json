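{
 "id": "erk1_activation_synthetic",
 "name": "ERK1 activation (synthetic reconstruction)",
 "entities": [
  {"id": "ERK1", "name": "ERK-1", "kind": "protein", "components": [],
   "description": "extracellular signal-regulated kinase 1"},
  {"id": "PMEK1S", "name": "p-S218,222-MEK1", "kind": "protein", "components": [],
   "description": "MEK1 phosphorylated at S218 and S222"},
  {"id": "PERK1", "name": "p-T202,Y204-ERK1", "kind": "protein", "components": [],
   "description": "doubly phosphorylated ERK-1"},
  {"id": "MEK1", "name": "MEK1", "kind": "protein", "components": [],
   "description": "MAP kinase kinase 1, unphosphorylated"},
  {"id": "PMEK1", "name": "p-MEK1", "kind": "protein", "components": [],
   "description": "singly phosphorylated MEK1"},
  {"id": "ATP", "name": "ATP", "kind": "small_molecule", "components": [],
   "description": "adenosine triphosphate"},
  {"id": "ADP", "name": "ADP", "kind": "small_molecule", "components": [],
   "description": "adenosine diphosphate"},
  {"id": "CPX_ERK1_PMEK1", "name": "ERK1:p-S218,222-MEK1", "kind": "complex",
   "components": ["ERK1", "PMEK1S"],
   "description": "kinase substrate complex of ERK-1 with phospho-MEK1"},
  {"id": "CPX_PERK1_PMEK1", "name": "p-ERK1:p-S218,222-MEK1", "kind": "complex",
   "components": ["PERK1", "PMEK1S"],
   "description": "complex of phospho-ERK-1 with phospho-MEK1"},
  {"id": "CPX_PERK1_DIMER", "name": "phospho-ERK-1 dimer", "kind": "complex",
   "components": ["PERK1"],
   "description": "homodimer of phosphorylated ERK-1"},
  {"id": "CPX_PERK1_DIMER_NUC", "name": "phospho-ERK-1 dimer (nucleus)",
   "kind": "complex", "components": ["PERK1"],
   "description": "nuclear phospho-ERK-1 dimer"}
 ],
 "reactions": [
  {"id": "R1", "name": "MEK1 binds ERK-1",
   "inputs": ["PMEK1S", "ERK1"], "outputs": ["CPX_ERK1_PMEK1"],
   "description": "phospho-MEK1 binds ERK-1 forming a kinase substrate complex"},
  {"id": "R2", "name": "Phosphorylation of ERK-1 by p-MEK1",
   "inputs": ["CPX_ERK1_PMEK1", "ATP"], "outputs": ["CPX_PERK1_PMEK1", "ADP"],
   "description": "p-MEK1 phosphorylates ERK-1 within the complex"},
  {"id": "R3", "name": "Dissociation of phospho-ERK-1:MEK1",
   "inputs": ["CPX_PERK1_PMEK1"], "outputs": ["PERK1", "PMEK1S"],
   "description": "dissociation of the complex releases phospho-ERK-1 and phospho-MEK1"},
  {"id": "R4", "name": "Dimerisation of phospho-ERK-1",
   "inputs": ["PERK1"], "outputs": ["CPX_PERK1_DIMER"],
   "description": "phospho-ERK-1 dimerises"},
  {"id": "R5", "name": "Translocation of phospho-ERK-1 dimer to the nucleus",
   "inputs": ["CPX_PERK1_DIMER"], "outputs": ["CPX_PERK1_DIMER_NUC"],
   "description": "the phospho-ERK-1 dimer translocates to the nucleus"},
  {"id": "R6", "name": "Phosphorylation of MEK1",
   "inputs": ["MEK1", "ATP"], "outputs": ["PMEK1", "ADP"],
   "description": "upstream kinase phosphorylates MEK1"}
 ],
 "controls": [
  {"controller": "PMEK1S", "controlled": "R2", "effect": "catalysis"}
 ]
}
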