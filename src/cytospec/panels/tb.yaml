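# PBMC T/B panel: 27 marker fluorophores over 48 detectors, plus viability.
# Gating encodes the published T- and B-cell hierarchy; populations listed
# earlier win depth ties during canonical assignment, so the more specific
# gates (Tregs, Th subsets, plasmablasts, MDSC-like blocks) come first.
panel: tb
name: "PBMC T/B panel"
detectors: 48
cofactor: 6000
signatures: tb_signatures_synthetic.csv

fluorophores:
  - {fluorophore: B548,   marker: CD45}
  - {fluorophore: R840,   marker: CD3}
  - {fluorophore: YG584,  marker: CD4}
  - {fluorophore: V570,   marker: CD8}
  - {fluorophore: R685,   marker: CD45RA}
  - {fluorophore: BYG781, marker: CD197}
  - {fluorophore: B610,   marker: CD27}
  - {fluorophore: V605,   marker: CD28}
  - {fluorophore: BYG575, marker: CD25}
  - {fluorophore: R660,   marker: CD127}
  - {fluorophore: B690,   marker: CD183}
  - {fluorophore: V655,   marker: CD196}
  - {fluorophore: YG610,  marker: CD194}
  - {fluorophore: B515,   marker: CD161}
  - {fluorophore: V785,   marker: CD185}
  - {fluorophore: V510,   marker: TCRab}
  - {fluorophore: BYG710, marker: TCRgd}
  - {fluorophore: R780,   marker: HLA-DR}
  - {fluorophore: R720,   marker: CD38}
  - {fluorophore: B750,   marker: CD19}
  - {fluorophore: B675,   marker: CD20}
  - {fluorophore: V445,   marker: IgD}
  - {fluorophore: R755,   marker: CD279}
  - {fluorophore: V747,   marker: CD366}
  - {fluorophore: YG670,  marker: CD223}
  - {fluorophore: B780,   marker: CD152}
  - {fluorophore: V450,   marker: CD123}

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
  - name: Lymphocytes
    parent: root
    canonical: false
    expr:
      rect: {x_channel: FSC-A, x_min: 28000, x_max: 66000,
             y_channel: SSC-A, y_min: 0, y_max: 32000}

  - {name: "Total T cells", parent: Lymphocytes, expr: "CD3+"}

  - {name: "CD8 T cells", parent: "Total T cells", expr: "CD4- CD8+"}
  - {name: "Naive CD8", parent: "CD8 T cells", expr: "CD45RA+ CD197+"}
  - {name: "TEMRA CD8", parent: "CD8 T cells", expr: "CD45RA+ CD197-"}
  - {name: "CD45RA terminal effector CD8", parent: "TEMRA CD8", expr: "CD27- CD28-"}
  - {name: "Central memory CD8", parent: "CD8 T cells", expr: "CD45RA- CD197+"}
  - {name: "Effector CD8", parent: "CD8 T cells", expr: "CD45RA- CD197-"}
  - {name: "Early effector CD8", parent: "Effector CD8", expr: "CD28+ CD27+"}
  - {name: "Early-like effector CD8", parent: "Effector CD8", expr: "CD28+ CD27-"}
  - {name: "Terminal effector CD8", parent: "Effector CD8", expr: "CD28- CD27-"}
  - {name: "Intermediate effector CD8", parent: "Effector CD8", expr: "CD28- CD27+"}

  - {name: "CD4 T cells", parent: "Total T cells", expr: "CD8- CD4+"}
  - {name: "Regulatory T cells", parent: "CD4 T cells", expr: "CD25+ CD127-"}
  - {name: "Th1", parent: "CD4 T cells", expr: "CD183+ CD196-"}
  - {name: "Th2", parent: "CD4 T cells", expr: "CD194+ CD196-"}
  - {name: "Th9/22", parent: "CD4 T cells", expr: "CD183- CD196+ CD194+"}
  - {name: "Th17", parent: "CD4 T cells", expr: "CD161+ CD196+"}
  - {name: "Naive CD4", parent: "CD4 T cells", expr: "CD45RA+ CD197+"}
  - {name: "TEMRA CD4", parent: "CD4 T cells", expr: "CD45RA+ CD197-"}
  - {name: "CD45RA terminal effector CD4", parent: "TEMRA CD4", expr: "CD27- CD28-"}
  - {name: "Central memory CD4", parent: "CD4 T cells", expr: "CD45RA- CD197+"}
  - {name: "Follicular helper T", parent: "Central memory CD4", expr: "CD185+ CD183all"}
  - {name: "Effector CD4", parent: "CD4 T cells", expr: "CD45RA- CD197-"}
  - {name: "Early effector CD4", parent: "Effector CD4", expr: "CD28+ CD27+"}
  - {name: "Early-like effector CD4", parent: "Effector CD4", expr: "CD28+ CD27-"}
  - {name: "Terminal effector CD4", parent: "Effector CD4", expr: "CD28- CD27-"}
  - {name: "Intermediate effector CD4", parent: "Effector CD4", expr: "CD28- CD27+"}

  - {name: "Gamma delta T cells", parent: "Total T cells", expr: "TCRgd+"}
  - {name: "TCRgd CD197- CD45RAhi", parent: "Gamma delta T cells", expr: "CD197- CD45RAhi"}
  - {name: "TCRgd CD197+", parent: "Gamma delta T cells", expr: "CD197+ CD45RAall"}
  - {name: "TCRgd CD197- CD45RA-", parent: "Gamma delta T cells", expr: "CD197- CD45RA-"}

  - {name: "NKT-like T cells", parent: "Total T cells", expr: "TCRgd- CD161+"}

  - {name: "NK cells", parent: Lymphocytes, expr: "CD3- TCRgd- TCRab- HLA-DR-"}

  - {name: "Total B cells", parent: Lymphocytes, expr: "CD19+"}
  - {name: "Plasmablasts", parent: "Total B cells", expr: "CD27+ CD38+"}
  - {name: "CD20+ B cells", parent: "Total B cells", expr: "CD20+"}
  - {name: "Naive B", parent: "CD20+ B cells", expr: "CD27- IgD+"}
  - {name: "Switched memory B", parent: "CD20+ B cells", expr: "CD27+ IgD-"}
  - {name: "Unswitched memory B", parent: "CD20+ B cells", expr: "CD27+ IgD+"}
  - {name: "DN memory B", parent: "CD20+ B cells", expr: "CD27- IgD-"}

overlays:
  - {name: "Activated T cells", base: "Total T cells", expr: "CD38+ HLA-DR+"}
  - {name: "PD-1+", base: "Total T cells", expr: "CD279+"}
  - {name: "TIM-3+", base: "Total T cells", expr: "CD366+"}
  - {name: "LAG-3+", base: "Total T cells", expr: "CD223+"}
  - {name: "CTLA-4+", base: "Total T cells", expr: "CD152+"}

template_baseline: {CD45: pos}

# Tregs and Th subsets generate with a central-memory-like CD197+ phenotype so
# their default templates do not collapse into the effector CD27/CD28 quadrants;
# B-cell templates carry HLA-DR (constitutive on B cells) so they stay out of
# the negatively-selected NK gate.
template_overrides:
  "Regulatory T cells": {CD197: pos}
  "Th1": {CD197: pos}
  "Th2": {CD197: pos}
  "Th9/22": {CD197: pos}
  "Th17": {CD197: pos}
  "Plasmablasts": {HLA-DR: pos}
  "Naive B": {HLA-DR: pos}
  "Switched memory B": {HLA-DR: pos}
  "Unswitched memory B": {HLA-DR: pos}
  "DN memory B": {HLA-DR: pos}

default_frequencies:
  "Naive CD8": 0.05
  "Central memory CD8": 0.025
  "CD45RA terminal effector CD8": 0.015
  "Early effector CD8": 0.015
  "Early-like effector CD8": 0.007
  "Terminal effector CD8": 0.012
  "Intermediate effector CD8": 0.006
  "Naive CD4": 0.09
  "Central memory CD4": 0.06
  "Follicular helper T": 0.015
  "CD45RA terminal effector CD4": 0.008
  "Early effector CD4": 0.02
  "Early-like effector CD4": 0.007
  "Terminal effector CD4": 0.012
  "Intermediate effector CD4": 0.008
  "Regulatory T cells": 0.025
  "Th1": 0.03
  "Th2": 0.02
  "Th9/22": 0.008
  "Th17": 0.017
  "Total T cells": 0.015
  "TCRgd CD197- CD45RAhi": 0.005
  "TCRgd CD197+": 0.008
  "TCRgd CD197- CD45RA-": 0.012
  "NKT-like T cells": 0.02
  "NK cells": 0.10
  "Plasmablasts": 0.005
  "Naive B": 0.04
  "Switched memory B": 0.018
  "Unswitched memory B": 0.012
  "DN memory B": 0.005

extra_templates:
  - name: "Monocytes (ungated)"
    frequency: 0.30
    scatter: monocyte
    levels: {CD45: pos, HLA-DR: pos}
  - name: "Basophils"
    frequency: 0.003
    scatter: lymphocyte
    levels: {CD45: int, CD123: hi}
  - name: "ILCs"
    frequency: 0.003
    scatter: lymphocyte
    levels: {CD45: pos, CD127: pos}
  - name: "DP T (CD4hi CD8lo)"
    frequency: 0.002
    scatter: lymphocyte
    levels: {CD45: pos, CD3: pos, CD4: hi, CD8: pos}
  - name: "DP T (CD4lo CD8hi)"
    frequency: 0.002
    scatter: lymphocyte
    levels: {CD45: pos, CD3: pos, CD4: pos, CD8: hi}
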