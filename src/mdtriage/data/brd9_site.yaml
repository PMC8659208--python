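# BRD9 bromodomain acetyl-lysine pocket definition.
# pocket_residues: residues lining the binding site, used for site RMSD and
# per-residue energy site sums; key_residues: the subset regarded as crucial
# for ligand binding, used for contact counting and RMSF violations.
# The key set is carried as given for the target and is not forced to be a
# subset of the pocket list (Ala46 belongs only to the key set).
target_name: BRD9
pocket_residues:
  - Gly43
  - Phe44
  - Phe45
  - Phe47
  - Pro48
  - Val49
  - Ile53
  - Ala54
  - Pro55
  - Tyr57
  - Met92
  - Asn95
  - Ala96
  - Met97
  - Tyr99
  - Asn100
  - Arg101
  - Thr104
  - Tyr106
key_residues:
  - Phe44
  - Phe45
  - Ala46
  - Val49
  - Ile53
  - Tyr99
  - Asn100
  - Arg101
  - Tyr106
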