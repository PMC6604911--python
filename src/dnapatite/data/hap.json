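{
  "name": "HAp",
  "formula": "Ca10(PO4)6(OH)2",
  "space_group": "P6_3/m",
  "comment": [
    "Hydroxyapatite, hexagonal P6_3/m (no. 176).",
    "Lattice constants a=b=9.42, c=6.87 A (gamma=120 deg).",
    "Asymmetric-unit fractional coordinates from the single-crystal refinements of",
    "Kay, Young & Posner, Nature 204 (1964) 1050 and Hughes, Cameron & Crowley,",
    "Am. Mineral. 74 (1989) 870.  The column hydroxyl is disordered about the",
    "mirror plane at z=1/4 (occupancy 1/2); the H site is tied to its oxygen.",
    "Partial charges (e): formal ionic Ca2+/OH-; PO4 split P +1.300 / O -1.075",
    "summing to -3 per tetrahedron; OH split O -1.400 / H +0.400."
  ],
  "lattice": {"a": 9.42, "b": 9.42, "c": 6.87, "alpha": 90.0, "beta": 90.0, "gamma": 120.0},
  "sites": [
    {"label": "Ca1", "element": "Ca", "frac": [0.333333333333, 0.666666666667, 0.0010], "occupancy": 1.0, "charge": 2.0},
    {"label": "Ca2", "element": "Ca", "frac": [0.2466, 0.9931, 0.25], "occupancy": 1.0, "charge": 2.0},
    {"label": "P",   "element": "P",  "frac": [0.3982, 0.3682, 0.25], "occupancy": 1.0, "charge": 1.3},
    {"label": "O1",  "element": "O",  "frac": [0.3283, 0.4846, 0.25], "occupancy": 1.0, "charge": -1.075},
    {"label": "O2",  "element": "O",  "frac": [0.5876, 0.4652, 0.25], "occupancy": 1.0, "charge": -1.075},
    {"label": "O3",  "element": "O",  "frac": [0.3433, 0.2579, 0.0702], "occupancy": 1.0, "charge": -1.075},
    {"label": "OH",  "element": "O",  "frac": [0.0, 0.0, 0.1978], "occupancy": 0.5, "charge": -1.4},
    {"label": "HO",  "element": "H",  "frac": [0.0, 0.0, 0.0580], "occupancy": 0.5, "charge": 0.4}
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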