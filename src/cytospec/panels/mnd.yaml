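# PBMC M/N/D panel: monocytes, NK, NKT and dendritic cells.
# 25 marker fluorophores over 48 detectors, plus viability.  The lymphocyte
# and monocyte scatter gates split the hierarchy as in the published
# strategy; MDSC-like gates precede the monocyte subsets so depth ties
# resolve toward the more specific population.
panel: mnd
name: "PBMC monocyte/NK/DC panel"
detectors: 48
cofactor: 6000
signatures: mnd_signatures_synthetic.csv

fluorophores:
  - {fluorophore: B548,   marker: CD45}
  - {fluorophore: R840,   marker: CD3}
  - {fluorophore: YG610,  marker: CD56}
  - {fluorophore: BYG710, marker: CD19}
  - {fluorophore: B675,   marker: CD20}
  - {fluorophore: R720,   marker: CD14}
  - {fluorophore: B677,   marker: CD16}
  - {fluorophore: V510,   marker: CD7}
  - {fluorophore: V570,   marker: CD94}
  - {fluorophore: R685,   marker: CD314}
  - {fluorophore: BYG575, marker: CD159c}
  - {fluorophore: B610,   marker: CD337}
  - {fluorophore: V605,   marker: CD335}
  - {fluorophore: YG670,  marker: CD336}
  - {fluorophore: B690,   marker: CD158}
  - {fluorophore: V747,   marker: CD366}
  - {fluorophore: B515,   marker: CD11b}
  - {fluorophore: R659,   marker: CD33}
  - {fluorophore: R780,   marker: HLA-DR}
  - {fluorophore: V450,   marker: CD123}
  - {fluorophore: V655,   marker: CD141}
  - {fluorophore: B750,   marker: CD1c}
  - {fluorophore: V785,   marker: CD5}
  - {fluorophore: V610,   marker: CD163}
  - {fluorophore: R755,   marker: CD11c}

viability: {fluorophore: VRed, marker: ViaDyeRed}

scatter_channels: [FSC-A, FSC-H, SSC-A]

cutoffs:
  default: {positive: 500, hi: 10000, int: [200, 2000]}

# The published workflow applied a -2.79 percent correction from the CD159c
# conjugate into the CD19 conjugate after unmixing; the shipped synthetic
# spectra need no correction, so the matrix ships empty and the entry below
# documents the convention:
#   - {source: CD159c, target: CD19, percent: -2.79}
compensation: []

pregates:
  singlet_band: 0.15
  scatter_min_fsc: 25000
  scatter_min_ssc: 1000

gates:
  - name: Lymphocytes
    parent: root
    canonical: false
    expr:
      rect: {x_channel: FSC-A, x_min: 28000, x_max: 66000,
             y_channel: SSC-A, y_min: 0, y_max: 32000}
  - name: Monocytes
    parent: root
    canonical: false
    expr:
      rect: {x_channel: FSC-A, x_min: 66000, x_max: 140000,
             y_channel: SSC-A, y_min: 18000, y_max: 85000}

  - {name: "NKT cells", parent: Lymphocytes, expr: "CD3+ CD56+"}
  - {name: "NK cells", parent: Lymphocytes, expr: "CD3- CD19- CD14- CD7+"}
  - {name: "Early NK cells", parent: "NK cells", expr: "CD56+ CD16-"}
  - {name: "Mature NK cells", parent: "NK cells", expr: "CD56+ CD16+"}
  - {name: "Terminal NK cells", parent: "NK cells", expr: "CD56- CD16+"}

  - {name: "MDSC-like cells", parent: Monocytes, expr: "CD11b+ CD33+ HLA-DR-"}
  - {name: "Monocytic MDSC-like cells", parent: "MDSC-like cells", expr: "CD14+"}

  - {name: "Classical monocytes", parent: Monocytes, expr: "CD14+ CD16-"}
  - {name: "Classical monocytes-Normal", parent: "Classical monocytes", expr: "HLA-DR+"}
  - {name: "Classical monocytes-Immunosuppressed", parent: "Classical monocytes",
     expr: "HLA-DR-"}
  - {name: "Intermediate monocytes", parent: Monocytes, expr: "CD14+ CD16+"}
  - {name: "Intermediate monocytes-Normal", parent: "Intermediate monocytes", expr: "HLA-DR+"}
  - {name: "Intermediate monocytes-Immunosuppressed", parent: "Intermediate monocytes",
     expr: "HLA-DR-"}
  - {name: "Nonclassical monocytes", parent: Monocytes, expr: "CD14- CD16+"}
  - {name: "Nonclassical monocytes-Normal", parent: "Nonclassical monocytes", expr: "HLA-DR+"}
  - {name: "Nonclassical monocytes-Immunosuppressed", parent: "Nonclassical monocytes",
     expr: "HLA-DR-"}

  - {name: "Dendritic cells", parent: Monocytes, expr: "CD3- HLA-DR+ CD19- CD20-"}
  - {name: "cDC1", parent: "Dendritic cells", expr: "CD14- CD123- CD141+ CD1c- CD5-"}
  - {name: "cDC2", parent: "Dendritic cells", expr: "CD14- CD123- CD141- CD1c+ CD5+ CD11b+"}
  - {name: "cDC3", parent: "Dendritic cells", expr: "CD163+ CD5- CD141- CD1c- CD123-"}
  - {name: "pDC", parent: "Dendritic cells", expr: "CD14- CD123+ CD141- CD1c- CD5-"}

overlays:
  - {name: "KLRD1+", base: "NK cells", expr: "CD94+"}
  - {name: "NKG2D+", base: "NK cells", expr: "CD314+"}
  - {name: "NKG2C+", base: "NK cells", expr: "CD159c+"}
  - {name: "NKp30+", base: "NK cells", expr: "CD337+"}
  - {name: "NKp46+", base: "NK cells", expr: "CD335+"}
  - {name: "NKp44+", base: "NK cells", expr: "CD336+"}
  - {name: "KIR+", base: "NK cells", expr: "CD158+"}
  - {name: "TIM-3+", base: "NK cells", expr: "CD366+"}

template_baseline: {CD45: pos}

template_overrides: {}

default_frequencies:
  "NKT cells": 0.02
  "Early NK cells": 0.02
  "Mature NK cells": 0.07
  "Terminal NK cells": 0.01
  "MDSC-like cells": 0.005
  "Monocytic MDSC-like cells": 0.01
  "Classical monocytes-Normal": 0.155
  "Classical monocytes-Immunosuppressed": 0.02
  "Intermediate monocytes-Normal": 0.03
  "Intermediate monocytes-Immunosuppressed": 0.005
  "Nonclassical monocytes-Normal": 0.04
  "Nonclassical monocytes-Immunosuppressed": 0.005
  "cDC1": 0.003
  "cDC2": 0.01
  "cDC3": 0.004
  "pDC": 0.008

extra_templates:
  - name: "T cells (ungated)"
    frequency: 0.49
    scatter: lymphocyte
    levels: {CD45: pos, CD3: pos, CD7: pos, CD5: pos}
  - name: "B cells (ungated)"
    frequency: 0.09
    scatter: lymphocyte
    levels: {CD45: pos, CD19: pos, CD20: pos, HLA-DR: pos}
  - name: "Basophils"
    frequency: 0.005
    scatter: lymphocyte
    levels: {CD45: int, CD123: hi}
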