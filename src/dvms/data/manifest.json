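{
 "description": "benzene RHF/6-31G(d) orbitals (ideal D6h geometry) and determinant CAS-CI vectors computed from them",
 "geometry": {
  "r_cc_angstrom": 1.397,
  "r_ch_angstrom": 1.087,
  "point_group": "D6h",
  "plane": "xy",
  "c6_axis": "z"
 },
 "conventions": {
  "d_functions": "cartesian (6D), components individually normalized",
  "determinant_sign": "orbitals in ascending index order per spin, alpha block before beta",
  "mo_labels": "mo<n> = index in the parent RHF calculation"
 },
 "energies_hartree": {
  "rhf": -230.70184300010837,
  "casci_66_pi": -230.7603010087585,
  "casci_3018_valence": -230.74443222788116
 },
 "files": {
  "benzene_rhf_631gd.molden": {
   "sha256": "0c1c7d8154e656ed5b6dd9c95ca872a35c2f6aad6aa3b3cac2e918e5f5c72f7b",
   "bytes": 60974
  },
  "benzene_rhf.civec": {
   "sha256": "8c2df594fb2d4539c51e62c3c8551fe15d379a5270f15457e2c52d420d0d62a3",
   "bytes": 301
  },
  "benzene_cas66_pi.civec": {
   "sha256": "a2a226d7bb100aa561f7df856a885a7aec736932d76138dbb9fe7275c480d332",
   "bytes": 13886
  },
  "benzene_cas3018_valence.civec": {
   "sha256": "b367fc9ed6a97322390cb55cd2584b055bd187b9dd6076a5d024c7e8515ec4af",
   "bytes": 46791
  }
 }
}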