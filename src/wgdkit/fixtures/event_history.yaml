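# Curated evolutionary scenario for the TRPV gene family along the packaged
# species tree.  Branches are named by their child node; events on a branch
# apply in listed order.  The two basal WGD rounds sit on the two stem
# branches above the cyclostome/gnathostome split; extra 2R copies that left
# no descendants are modeled as early losses on the vertebrate stem.
wgd_tags:
  Vertebrata_1R: 1R
  Vertebrata: 2R
  Teleostei: 3R
  atlantic_salmon: 4R
root_repertoire:
  - name: TRPVC
    subtype: TRPVC
  - name: TRPVD
    subtype: TRPVD
events:
  # --- basal vertebrate WGDs (1R/2R) ---
  - branch: Vertebrata_1R
    kind: wgd
    tag: 1R
    renames:
      TRPVC: [TRPV1, TRPV4]
      TRPVD: [TRPV5, TRPV7]
    subtypes:
      TRPV1: TRPV1
      TRPV4: TRPV4
      TRPV5: TRPV5
      TRPV7: TRPV7
  - branch: Vertebrata
    kind: wgd
    tag: 2R
    renames:
      TRPV1: [TRPV1, TRPV1.2R2]
      TRPV4: [TRPV4, TRPV4.2R2]
      TRPV5: [TRPV5, TRPV5.2R2]
      TRPV7: [TRPV7, TRPV7.2R2]
  - {branch: Vertebrata, kind: loss, target: TRPV1.2R2}
  - {branch: Vertebrata, kind: loss, target: TRPV4.2R2}
  - {branch: Vertebrata, kind: loss, target: TRPV5.2R2}
  - {branch: Vertebrata, kind: loss, target: TRPV7.2R2}
  - branch: Vertebrata
    kind: local_duplication
    target: TRPV7
    copies: 1
    new_names: [TRPV8]
    subtypes:
      TRPV8: TRPV8

  # --- cyclostomes ---
  - {branch: sea_lamprey, kind: loss, target: TRPV1}
  - branch: sea_lamprey
    kind: local_duplication
    target: TRPV5
    copies: 1
    rename_target: cyTRPV5-1
    new_names: [cyTRPV5-2]
    name_rule: "prefix:cy"

  # --- gnathostome stem: local duplications producing TRPV3 and TRPV9 ---
  - branch: Gnathostomata
    kind: local_duplication
    target: TRPV1
    copies: 1
    new_names: [TRPV3]
    subtypes:
      TRPV3: TRPV3
  - branch: Gnathostomata
    kind: local_duplication
    target: TRPV3
    copies: 1
    new_names: [TRPV9]
    subtypes:
      TRPV9: TRPV9

  # --- chondrichthyans ---
  - branch: Chondrichthyes
    kind: local_duplication
    target: TRPV5
    copies: 2
    rename_target: chTRPV5-1
    new_names: [chTRPV5-2, chTRPV5-3]
    name_rule: "prefix:ch"
  - {branch: elephant_shark, kind: loss, target: TRPV9}
  - {branch: elephant_shark, kind: loss, target: chTRPV5-1}
  - {branch: whale_shark, kind: loss, target: chTRPV5-1}
  - branch: Elasmobranchii
    kind: local_duplication
    target: TRPV8
    copies: 1
    rename_target: TRPV8-1
    new_names: [TRPV8-2]

  # --- osteichthyans / actinopterygians ---
  - {branch: Osteichthyes, kind: loss, target: TRPV9}
  - {branch: Actinopterygii, kind: loss, target: TRPV3}
  - branch: Polypteridae
    kind: local_duplication
    target: TRPV5
    copies: 4
    rename_target: poTRPV5-1
    new_names: [poTRPV5-2, poTRPV5-3, poTRPV5-4, poTRPV5-5]
    name_rule: "prefix:po"
  - {branch: Neopterygii, kind: loss, target: TRPV7}
  - {branch: Neopterygii, kind: loss, target: TRPV8}

  # --- teleost WGD (3R); the TRPV4 and TRPV5 co-duplicates were lost on the
  #     teleost stem before the radiation ---
  - branch: Teleostei
    kind: wgd
    tag: 3R
    renames:
      TRPV1: [TRPV1a, TRPV1b]
      TRPV4: [TRPV4, TRPV4.3R2]
      TRPV5: [TRPV5, TRPV5.3R2]
  - {branch: Teleostei, kind: loss, target: TRPV4.3R2}
  - {branch: Teleostei, kind: loss, target: TRPV5.3R2}
  - {branch: european_eel, kind: loss, target: TRPV1b}
  - {branch: asian_bonytongue, kind: loss, target: TRPV1b}
  - {branch: zebrafish, kind: loss, target: TRPV1b}
  - {branch: Protacanthopterygii, kind: loss, target: TRPV1b}
  - branch: northern_pike
    kind: local_duplication
    target: TRPV5
    copies: 1
    rename_target: TRPV5-1
    new_names: [TRPV5-2]
  - branch: atlantic_salmon
    kind: wgd
    tag: 4R
    renames:
      TRPV1a: ["TRPV1aα", "TRPV1aβ"]
      TRPV4: ["TRPV4α", "TRPV4β"]
      TRPV5: ["TRPV5α", "TRPV5β"]
  - branch: atlantic_cod
    kind: local_duplication
    target: TRPV1a
    copies: 2
    rename_target: TRPV1a-1
    new_names: [TRPV1a-2, TRPV1a-3]
  - branch: atlantic_cod
    kind: local_duplication
    target: TRPV1b
    copies: 2
    rename_target: TRPV1b-1
    new_names: [TRPV1b-2, TRPV1b-3]

  # --- sarcopterygians ---
  - branch: coelacanth
    kind: local_duplication
    target: TRPV3
    copies: 2
    rename_target: TRPV3-1
    new_names: [TRPV3-2, TRPV3-3]
  - branch: Tetrapoda
    kind: local_duplication
    target: TRPV1
    copies: 1
    new_names: [TRPV2]
    subtypes:
      TRPV2: TRPV2
  - branch: Amphibia
    kind: local_duplication
    target: TRPV5
    copies: 3
    rename_target: amTRPV5-1
    new_names: [amTRPV5-2, amTRPV5-3, amTRPV5-4]
    name_rule: "prefix:am"
  - branch: Xenopus
    kind: local_duplication
    target: TRPV4
    copies: 2
    rename_target: TRPV4-1
    new_names: [TRPV4-2, TRPV4-3]
  - branch: xenopus_tropicalis
    kind: local_duplication
    target: TRPV4-1
    copies: 3
    new_names: [TRPV4-4, TRPV4-5, TRPV4-6]
  - branch: Mammalia
    kind: local_duplication
    target: TRPV5
    copies: 1
    rename_target: mTRPV5-1
    new_names: [mTRPV5-2]
    name_rule: "prefix:m"
  - {branch: platypus, kind: loss, target: mTRPV5-1}
  - {branch: Theria, kind: loss, target: TRPV7}
  - {branch: opossum, kind: pseudogenization, target: TRPV8}
  - {branch: human, kind: loss, target: TRPV8}
  - {branch: Sauropsida, kind: loss, target: TRPV7}
  - {branch: Sauropsida, kind: loss, target: TRPV8}
  - branch: Sauropsida
    kind: local_duplication
    target: TRPV5
    copies: 1
    rename_target: sauTRPV5-1
    new_names: [sauTRPV5-2]
    name_rule: "prefix:sau"
  - {branch: Aves, kind: pseudogenization, target: sauTRPV5-2}
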