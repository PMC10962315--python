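# Bone-marrow (BMC) panel: 32 marker fluorophores over 48 detectors, plus
# viability.  The hierarchy splits CD45+ cells into CD3+/CD34- T lymphocytes,
# CD3-/CD34+ progenitors and CD3-/CD34- mature cells; NK gates carry explicit
# CD14-/HLA-DR- exclusions and precede the monocyte gates so overlapping
# CD16+ definitions resolve to the more specific population.
panel: bmc
name: "Bone marrow cell panel"
detectors: 48
cofactor: 6000
signatures: bmc_signatures_synthetic.csv

fluorophores:
  - {fluorophore: B548,   marker: CD45}
  - {fluorophore: B650,   marker: CD3}
  - {fluorophore: V525,   marker: CD34}
  - {fluorophore: V510,   marker: TCRab}
  - {fluorophore: BYG710, marker: TCRgd}
  - {fluorophore: YG610,  marker: CD56}
  - {fluorophore: YG584,  marker: CD4}
  - {fluorophore: V570,   marker: CD8}
  - {fluorophore: R685,   marker: CD45RA}
  - {fluorophore: BYG781, marker: CD197}
  - {fluorophore: BYG575, marker: CD25}
  - {fluorophore: R660,   marker: CD127}
  - {fluorophore: R840,   marker: CD38}
  - {fluorophore: BYG610, marker: CD90}
  - {fluorophore: R780,   marker: CD10}
  - {fluorophore: B690,   marker: CD135}
  - {fluorophore: BB755,  marker: CD20}
  - {fluorophore: NFB610, marker: CD19}
  - {fluorophore: B677,   marker: CD16}
  - {fluorophore: V547,   marker: CD14}
  - {fluorophore: R720,   marker: HLA-DR}
  - {fluorophore: V450,   marker: CD123}
  - {fluorophore: R755,   marker: CD11c}
  - {fluorophore: R659,   marker: CD33}
  - {fluorophore: B515,   marker: CD11b}
  - {fluorophore: V605,   marker: CD274}
  - {fluorophore: V747,   marker: CD366}
  - {fluorophore: BYG750, marker: CD163}
  - {fluorophore: B610,   marker: CD206}
  - {fluorophore: V655,   marker: CD74}
  - {fluorophore: YG670,  marker: CD80}
  - {fluorophore: V785,   marker: CD86}

viability: {fluorophore: VRed, marker: ViaDyeRed}

scatter_channels: [FSC-A, FSC-H, SSC-A]

cutoffs:
  default: {positive: 500, hi: 10000, int: [200, 2000]}

compensation: []

pregates:
  singlet_band: 0.15
  scatter_min_fsc: 25000
  scatter_min_ssc: 1000

gates:
  - {name: "Total T cells", parent: root, expr: "CD3+ CD34-"}
  - {name: "Gamma delta T cells", parent: "Total T cells", expr: "TCRgd+"}
  - {name: "Alpha-beta T", parent: "Total T cells", canonical: false,
     expr: "TCRab+ TCRgd-"}
  - {name: "NKT cells", parent: "Alpha-beta T", expr: "CD56+"}
  - {name: "NKT CD8+", parent: "NKT cells", expr: "CD8+"}
  - {name: "NKT CD8-", parent: "NKT cells", expr: "CD8-"}
  - {name: "CD56- T", parent: "Alpha-beta T", canonical: false, expr: "CD56-"}
  - {name: "CD8 T cells", parent: "CD56- T", expr: "CD4- CD8+"}
  - {name: "Naive CD8", parent: "CD8 T cells", expr: "CD45RA+ CD197+"}
  - {name: "TEMRA CD8", parent: "CD8 T cells", expr: "CD45RA+ CD197-"}
  - {name: "Central memory CD8", parent: "CD8 T cells", expr: "CD45RA- CD197+"}
  - {name: "Effector CD8", parent: "CD8 T cells", expr: "CD45RA- CD197-"}
  - {name: "CD4 T cells", parent: "CD56- T", expr: "CD4+ CD8-"}
  - {name: "Regulatory T cells", parent: "CD4 T cells", expr: "CD25+ CD127-"}
  - {name: "Naive CD4", parent: "CD4 T cells", expr: "CD45RA+ CD197+"}
  - {name: "TEMRA CD4", parent: "CD4 T cells", expr: "CD45RA+ CD197-"}
  - {name: "Central memory CD4", parent: "CD4 T cells", expr: "CD45RA- CD197+"}
  - {name: "Effector CD4", parent: "CD4 T cells", expr: "CD45RA- CD197-"}

  - {name: "Progenitors", parent: root, canonical: false, expr: "CD3- CD34+"}
  - {name: "CD38- progenitors", parent: Progenitors, canonical: false, expr: "CD38-"}
  - {name: "HSC", parent: "CD38- progenitors", expr: "CD45RA- CD90+"}
  - {name: "MPP", parent: "CD38- progenitors", expr: "CD45RA- CD90-"}
  - {name: "MLP", parent: "CD38- progenitors", expr: "CD45RA+ CD90-"}
  - {name: "MLP I", parent: "MLP", expr: "CD10-"}
  - {name: "MLP II", parent: "MLP", expr: "CD10+"}
  - {name: "CD38+ progenitors", parent: Progenitors, canonical: false, expr: "CD38+"}
  - {name: "CD10+ Progenitors", parent: "CD38+ progenitors", expr: "CD10+"}
  - {name: "CD10- progenitors", parent: "CD38+ progenitors", canonical: false, expr: "CD10-"}
  - {name: "CMP", parent: "CD10- progenitors", expr: "CD45RA- CD135+"}
  - {name: "GMP", parent: "CD10- progenitors", expr: "CD45RA+ CD135+"}
  - {name: "MEP", parent: "CD10- progenitors", expr: "CD45RA- CD135-"}

  - {name: "CD3- CD34-", parent: root, canonical: false, expr: "CD3- CD34-"}
  - {name: "B cells", parent: "CD3- CD34-", expr: "CD19+ CD20+"}
  - {name: "Plasmablasts", parent: "CD3- CD34-", expr: "CD19+ CD20- CD38+"}
  - {name: "CD19- CD20-", parent: "CD3- CD34-", canonical: false, expr: "CD19- CD20-"}
  - {name: "Early NK", parent: "CD19- CD20-", expr: "CD56+ CD16- CD14- HLA-DR-"}
  - {name: "Mature NK", parent: "CD19- CD20-", expr: "CD56+ CD16+ CD14- HLA-DR-"}
  - {name: "Terminal NK", parent: "CD19- CD20-", expr: "CD56- CD16+ CD14- HLA-DR-"}
  - {name: "ILCs", parent: "CD19- CD20-", expr: "HLA-DR- CD14- CD123- CD127+"}
  - {name: "MDSC-like", parent: "CD19- CD20-", expr: "CD14+ HLA-DR- CD11b+ CD33+"}
  - {name: "Nonclassical monocytes", parent: "CD19- CD20-", expr: "CD14- CD16+"}
  - {name: "Classical monocytes", parent: "CD19- CD20-", expr: "CD14+ CD16-"}
  - {name: "Dendritic cells", parent: "CD19- CD20-", expr: "HLA-DR+ CD14-"}
  - {name: "pDC", parent: "Dendritic cells", expr: "CD11c- CD123+"}
  - {name: "CD16+ cDC", parent: "Dendritic cells", expr: "CD11c+ CD123- CD16+"}
  - {name: "CD16- cDC", parent: "Dendritic cells", expr: "CD11c+ CD123- CD16-"}

overlays:
  - {name: "PD-L1+", base: "Classical monocytes", expr: "CD274+"}
  - {name: "TIM-3+", base: "Total T cells", expr: "CD366+"}
  - {name: "CD163+ macrophage-like", base: "Classical monocytes", expr: "CD163+"}
  - {name: "CD206+", base: "Classical monocytes", expr: "CD206+"}
  - {name: "CD74+", base: "Dendritic cells", expr: "CD74+"}
  - {name: "CD80+", base: "Dendritic cells", expr: "CD80+"}
  - {name: "CD86+", base: "Dendritic cells", expr: "CD86+"}

template_baseline: {CD45: pos}

template_overrides:
  "Regulatory T cells": {CD197: pos}
  "Nonclassical monocytes": {HLA-DR: pos}
  "Classical monocytes": {HLA-DR: pos}

default_frequencies:
  "Total T cells": 0.01
  "Gamma delta T cells": 0.01
  "NKT CD8+": 0.005
  "NKT CD8-": 0.005
  "Naive CD8": 0.02
  "TEMRA CD8": 0.01
  "Central memory CD8": 0.015
  "Effector CD8": 0.02
  "Naive CD4": 0.03
  "TEMRA CD4": 0.005
  "Central memory CD4": 0.02
  "Effector CD4": 0.015
  "Regulatory T cells": 0.01
  "HSC": 0.002
  "MPP": 0.004
  "MLP I": 0.003
  "MLP II": 0.002
  "CMP": 0.012
  "GMP": 0.012
  "MEP": 0.012
  "CD10+ Progenitors": 0.013
  "B cells": 0.08
  "Plasmablasts": 0.005
  "Early NK": 0.015
  "Mature NK": 0.04
  "Terminal NK": 0.01
  "ILCs": 0.003
  "MDSC-like": 0.012
  "Nonclassical monocytes": 0.03
  "Classical monocytes": 0.14
  "pDC": 0.006
  "CD16+ cDC": 0.005
  "CD16- cDC": 0.009

extra_templates:
  - name: "CD45- erythroid/other (ungated)"
    frequency: 0.41
    scatter: lymphocyte
    levels: {}
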