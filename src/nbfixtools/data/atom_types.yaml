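# Van der Waals atom types entering the 0BPh NBfix correction.
#
# rmin_half: minimum-energy radius contribution, Å
# eps:       well depth, kcal/mol
# role:      which 0BPh partner the type represents
#
# H5 is the AMBER type of purine H8, H4 the type of pyrimidine H6.
# OR covers the O5'/O3' bridging phosphate oxygens of the RNA OL3_CP
# force field (phosphate vdW revision); OS covers O5'/O3'/O4' in DNA
# OL15.  O3' (and O4' for DNA) share the bridging-oxygen type and
# therefore inherit any NBfix applied to it; these partners sit farther
# from H8/H6 and the effect is marginal.
version: 1
atom_types:
  H5:
    rmin_half: 1.3590
    eps: 0.0150
    role: purine-H8
  H4:
    rmin_half: 1.4090
    eps: 0.0150
    role: pyrimidine-H6
  OR:
    rmin_half: 1.7718
    eps: 0.1700
    role: bridging-O-RNA
  OS:
    rmin_half: 1.6837
    eps: 0.1700
    role: bridging-O-DNA
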