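# Default signature catalog: 31 copper-related protein types of beta-proteobacterial
# proteomes, grouped in three sections (cuproprotein / homeostasis / chaperone).
# Dual-membership types carry both categories. Domain ids pair a Pfam domain name
# with its accession; "CSP" is a custom profile built from four-helix-bundle
# copper-storage proteins and has no Pfam accession.
version: "1.0"
types:
  # ---- cuproproteins -------------------------------------------------------
  - type_name: "Nitrite reductase"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: architecture
    domain_ids:
      - {name: Cu-oxidase, accession: PF00394}
      - {name: Cu-oxidase_2, accession: PF07731}
      - {name: Cu-oxidase_3, accession: PF07732}
      - {name: Copper-bind, accession: PF00127}
      - {name: Cytochrome_CBB3, accession: PF13442}
    patterns:
      - {elements: [Cu-oxidase_3, Cu-oxidase], scope: same_protein}
      - {elements: [Cu-oxidase_3, Cytochrome_CBB3], scope: split_complex}
      - {elements: [Copper-bind, Cu-oxidase_3], scope: same_protein}
      - {elements: [Copper-bind, Cu-oxidase_3, Cu-oxidase_2], scope: same_protein}
  - type_name: "Nitrous oxide Reductase"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: nos_propeller, accession: PF18764}
  - type_name: "Nnrs"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: NnrS, accession: PF05940}
  - type_name: "Copper-bind"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: Copper-bind, accession: PF00127}
  - type_name: "Cu_amine_oxid"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: Cu_amine_oxid, accession: PF01179}
  - type_name: "Cu-oxidase_4"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: Cu-oxidase_4, accession: PF02578}
  - type_name: "Cupredoxin_1"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: Cupredoxin_1, accession: PF13473}
  - type_name: "DUF386"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: DUF386, accession: PF04074}
  - type_name: "Monooxygenase_B"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: Monooxygenase_B, accession: PF04744}
  - type_name: "Sod_Cu"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: Sod_Cu, accession: PF00080}
  - type_name: "Tyrosinase"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: single_domain
    domain_ids:
      - {name: Tyrosinase, accession: PF00264}
  - type_name: "Cyto_bo"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: complex
    domain_ids:
      - {name: COX1, accession: PF00115}
      - {name: COX2, accession: PF00116}
    patterns:
      - {elements: [COX1, COX2], scope: split_complex}
    params: {required_flag: CyoB}
  - type_name: "Cyto_C_aa3"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: complex
    domain_ids:
      - {name: COX1, accession: PF00115}
      - {name: COX2, accession: PF00116}
    patterns:
      - {elements: [COX1, COX2], scope: split_complex}
    params: {required_flag: QoxB}
  - type_name: "Cyto_C_cbb3"
    section: cuproprotein
    categories: [cuproprotein]
    match_mode: complex
    domain_ids:
      - {name: COX1, accession: PF00115}
      - {name: FixO, accession: PF02433}
    patterns:
      - {elements: [COX1, FixO], scope: split_complex}
  # ---- copper homeostasis --------------------------------------------------
  - type_name: "MCOs"
    section: homeostasis
    categories: [cuproprotein, homeostasis]
    match_mode: architecture
    domain_ids:
      - {name: Cu-oxidase, accession: PF00394}
      - {name: Cu-oxidase_2, accession: PF07731}
      - {name: Cu-oxidase_3, accession: PF07732}
    patterns:
      - {elements: [Cu-oxidase_3, Cu-oxidase, Cu-oxidase_2], scope: same_protein}
      - {elements: [Cu-oxidase_3, Cu-oxidase_2], scope: same_protein}
      - {elements: [Cu-oxidase_3, Cu-oxidase_2], scope: split_complex}
  - type_name: "Cu ATPases"
    section: homeostasis
    categories: [homeostasis]
    match_mode: transporter_disambiguation
    domain_ids:
      - {name: E1-E2_ATPases, accession: PF00122}
    params: {family: P_type_ATPase, target_label: "3.A.3.5", excluded_label: "3.A.3.27"}
  - type_name: "RNDs HME"
    section: homeostasis
    categories: [homeostasis]
    match_mode: transporter_disambiguation
    domain_ids:
      - {name: ACR_tran, accession: PF00873}
    params: {family: RND, target_label: "2.A.6.1"}
  - type_name: "CopB"
    section: homeostasis
    categories: [homeostasis]
    match_mode: single_domain
    domain_ids:
      - {name: CopB, accession: PF05275}
  - type_name: "CopC"
    section: homeostasis
    categories: [homeostasis]
    match_mode: single_domain
    domain_ids:
      - {name: CopC, accession: PF04234}
  - type_name: "CopD"
    section: homeostasis
    categories: [homeostasis]
    match_mode: single_domain
    domain_ids:
      - {name: CopD, accession: PF05425}
  - type_name: "CopK"
    section: homeostasis
    categories: [homeostasis]
    match_mode: single_domain
    domain_ids:
      - {name: CopK, accession: PF11525}
  - type_name: "CutA1"
    section: homeostasis
    categories: [homeostasis]
    match_mode: single_domain
    domain_ids:
      - {name: CutA1, accession: PF03091}
  - type_name: "CutC"
    section: homeostasis
    categories: [homeostasis]
    match_mode: single_domain
    domain_ids:
      - {name: CutC, accession: PF03932}
  # ---- copper chaperones ---------------------------------------------------
  - type_name: "Csp3_Ccsp"
    section: chaperone
    categories: [homeostasis, chaperone]
    match_mode: csp_cytoplasmic
    domain_ids:
      - {name: DUF326, accession: PF02860}
      - {name: CSP, accession: CSP}
  - type_name: "CusF_EC"
    section: chaperone
    categories: [chaperone]
    match_mode: single_domain
    domain_ids:
      - {name: CusF_EC, accession: PF11604}
  - type_name: "HMA"
    section: chaperone
    categories: [chaperone]
    match_mode: single_domain
    domain_ids:
      - {name: HMA, accession: PF00403}
  - type_name: "PCuAC"
    section: chaperone
    categories: [chaperone]
    match_mode: single_domain
    domain_ids:
      - {name: PCuAC, accession: PF04314}
  - type_name: "SCO1-SenC"
    section: chaperone
    categories: [chaperone]
    match_mode: single_domain
    domain_ids:
      - {name: SCO1-SenC, accession: PF02630}
  - type_name: "Csp1/2_Ecsp"
    section: chaperone
    categories: [chaperone]
    match_mode: csp_extracytoplasmic
    domain_ids:
      - {name: DUF326, accession: PF02860}
      - {name: CSP, accession: CSP}
  - type_name: "CtaG_COX11"
    section: chaperone
    categories: [chaperone]
    match_mode: single_domain
    domain_ids:
      - {name: CtaG_COX11, accession: PF04442}
  - type_name: "NosL"
    section: chaperone
    categories: [chaperone]
    match_mode: single_domain
    domain_ids:
      - {name: NosL, accession: PF05573}
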