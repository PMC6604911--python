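{
  "name": "FAp",
  "formula": "Ca10(PO4)6F2",
  "space_group": "P6_3/m",
  "comment": [
    "Fluoroapatite, hexagonal P6_3/m (no. 176), isostructural with hydroxyapatite",
    "with F- on the c-axis (2a site) replacing the disordered hydroxyl column.",
    "Lattice constants a=b=9.40, c=6.88 A (gamma=120 deg).",
    "Asymmetric-unit fractional coordinates from Hughes, Cameron & Crowley,",
    "Am. Mineral. 74 (1989) 870.",
    "Partial charges (e): Ca +2, F -1, PO4 split P +1.300 / O -1.075 (sum -3)."
  ],
  "lattice": {"a": 9.40, "b": 9.40, "c": 6.88, "alpha": 90.0, "beta": 90.0, "gamma": 120.0},
  "sites": [
    {"label": "Ca1", "element": "Ca", "frac": [0.333333333333, 0.666666666667, 0.0010], "occupancy": 1.0, "charge": 2.0},
    {"label": "Ca2", "element": "Ca", "frac": [0.2418, 0.9931, 0.25], "occupancy": 1.0, "charge": 2.0},
    {"label": "P",   "element": "P",  "frac": [0.3982, 0.3690, 0.25], "occupancy": 1.0, "charge": 1.3},
    {"label": "O1",  "element": "O",  "frac": [0.3251, 0.4849, 0.25], "occupancy": 1.0, "charge": -1.075},
    {"label": "O2",  "element": "O",  "frac": [0.5893, 0.4666, 0.25], "occupancy": 1.0, "charge": -1.075},
    {"label": "O3",  "element": "O",  "frac": [0.3412, 0.2580, 0.0703], "occupancy": 1.0, "charge": -1.075},
    {"label": "F",   "element": "F",  "frac": [0.0, 0.0, 0.25], "occupancy": 1.0, "charge": -1.0}
  ],
  "ops": [
    {"rot": [[1, 0, 0], [0, 1, 0], [0, 0, 1]], "trans": [0.0, 0.0, 0.0]},
    {"rot": [[0, -1, 0], [1, -1, 0], [0, 0, 1]], "trans": [0.0, 0.0, 0.0]},
    {"rot": [[-1, 1, 0], [-1, 0, 0], [0, 0, 1]], "trans": [0.0, 0.0, 0.0]},
    {"rot": [[-1, 0, 0], [0, -1, 0], [0, 0, 1]], "trans": [0.0, 0.0, 0.5]},
    {"rot": [[0, 1, 0], [-1, 1, 0], [0, 0, 1]], "trans": [0.0, 0.0, 0.5]},
    {"rot": [[1, -1, 0], [1, 0, 0], [0, 0, 1]], "trans": [0.0, 0.0, 0.5]},
    {"rot": [[-1, 0, 0], [0, -1, 0], [0, 0, -1]], "trans": [0.0, 0.0, 0.0]},
    {"rot": [[0, 1, 0], [-1, 1, 0], [0, 0, -1]], "trans": [0.0, 0.0, 0.0]},
    {"rot": [[1, -1, 0], [1, 0, 0], [0, 0, -1]], "trans": [0.0, 0.0, 0.0]},
    {"rot": [[1, 0, 0], [0, 1, 0], [0, 0, -1]], "trans": [0.0, 0.0, 0.5]},
    {"rot": [[0, -1, 0], [1, -1, 0], [0, 0, -1]], "trans": [0.0, 0.0, 0.5]},
    {"rot": [[-1, 1, 0], [-1, 0, 0], [0, 0, -1]], "trans": [0.0, 0.0, 0.5]}
  ]
}
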