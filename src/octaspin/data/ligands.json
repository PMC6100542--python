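{
  "comment": "Built-in ligand library: nine monodentate, six bidentate, one tetradentate ligand spanning the spectrochemical series from weak-field chloride to strong-field carbonyl. Atoms are element symbols (hydrogens included); bonds are [i, j, order]; connecting_atoms index the metal-binding atoms.",
  "ligands": [
    {
      "index": 1,
      "name": "Cl",
      "full_name": "chloride",
      "atoms": ["Cl"],
      "bonds": [],
      "connecting_atoms": [0],
      "charge": -1,
      "denticity": 1
    },
    {
      "index": 2,
      "name": "SCN",
      "full_name": "thiocyanate (S-bound)",
      "atoms": ["S", "C", "N"],
      "bonds": [[0, 1, 1], [1, 2, 3]],
      "connecting_atoms": [0],
      "charge": -1,
      "denticity": 1
    },
    {
      "index": 3,
      "name": "pisc",
      "full_name": "phenyl isocyanide",
      "atoms": ["C", "N", "C", "C", "C", "C", "C", "C", "H", "H", "H", "H", "H"],
      "bonds": [
        [0, 1, 3], [1, 2, 1],
        [2, 3, 1.5], [3, 4, 1.5], [4, 5, 1.5], [5, 6, 1.5], [6, 7, 1.5], [7, 2, 1.5],
        [3, 8, 1], [4, 9, 1], [5, 10, 1], [6, 11, 1], [7, 12, 1]
      ],
      "connecting_atoms": [0],
      "charge": 0,
      "denticity": 1
    },
    {
      "index": 4,
      "name": "misc",
      "full_name": "methyl isocyanide",
      "atoms": ["C", "N", "C", "H", "H", "H"],
      "bonds": [[0, 1, 3], [1, 2, 1], [2, 3, 1], [2, 4, 1], [2, 5, 1]],
      "connecting_atoms": [0],
      "charge": 0,
      "denticity": 1
    },
    {
      "index": 5,
      "name": "CN",
      "full_name": "cyanide",
      "atoms": ["C", "N"],
      "bonds": [[0, 1, 3]],
      "connecting_atoms": [0],
      "charge": -1,
      "denticity": 1
    },
    {
      "index": 6,
      "name": "CO",
      "full_name": "carbonyl",
      "atoms": ["C", "O"],
      "bonds": [[0, 1, 3]],
      "connecting_atoms": [0],
      "charge": 0,
      "denticity": 1
    },
    {
      "index": 7,
      "name": "NCS",
      "full_name": "isothiocyanate (N-bound)",
      "atoms": ["N", "C", "S"],
      "bonds": [[0, 1, 2], [1, 2, 2]],
      "connecting_atoms": [0],
      "charge": -1,
      "denticity": 1
    },
    {
      "index": 8,
      "name": "bipy",
      "full_name": "2,2'-bipyridine",
      "atoms": ["N", "C", "C", "C", "C", "C", "N", "C", "C", "C", "C", "C", "H", "H", "H", "H", "H", "H", "H", "H"],
      "bonds": [
        [0, 1, 1.5], [1, 2, 1.5], [2, 3, 1.5], [3, 4, 1.5], [4, 5, 1.5], [5, 0, 1.5],
        [6, 7, 1.5], [7, 8, 1.5], [8, 9, 1.5], [9, 10, 1.5], [10, 11, 1.5], [11, 6, 1.5],
        [1, 7, 1],
        [2, 12, 1], [3, 13, 1], [4, 14, 1], [5, 15, 1],
        [8, 16, 1], [9, 17, 1], [10, 18, 1], [11, 19, 1]
      ],
      "connecting_atoms": [0, 6],
      "charge": 0,
      "denticity": 2
    },
    {
      "index": 9,
      "name": "NH3",
      "full_name": "ammonia",
      "atoms": ["N", "H", "H", "H"],
      "bonds": [[0, 1, 1], [0, 2, 1], [0, 3, 1]],
      "connecting_atoms": [0],
      "charge": 0,
      "denticity": 1
    },
    {
      "index": 10,
      "name": "phen",
      "full_name": "1,10-phenanthroline",
      "atoms": ["N", "C", "C", "C", "C", "C", "C", "C", "C", "C", "C", "N", "C", "C", "H", "H", "H", "H", "H", "H", "H", "H"],
      "bonds": [
        [0, 1, 1.5], [1, 2, 1.5], [2, 3, 1.5], [3, 4, 1.5], [4, 13, 1.5], [13, 0, 1.5],
        [4, 5, 1.5], [5, 6, 1.5], [6, 7, 1.5], [7, 12, 1.5], [12, 13, 1.5],
        [7, 8, 1.5], [8, 9, 1.5], [9, 10, 1.5], [10, 11, 1.5], [11, 12, 1.5],
        [1, 14, 1], [2, 15, 1], [3, 16, 1], [5, 17, 1], [6, 18, 1], [8, 19, 1], [9, 20, 1], [10, 21, 1]
      ],
      "connecting_atoms": [0, 11],
      "charge": 0,
      "denticity": 2
    },
    {
      "index": 11,
      "name": "en",
      "full_name": "ethylenediamine",
      "atoms": ["N", "C", "C", "N", "H", "H", "H", "H", "H", "H", "H", "H"],
      "bonds": [
        [0, 1, 1], [1, 2, 1], [2, 3, 1],
        [0, 4, 1], [0, 5, 1], [1, 6, 1], [1, 7, 1], [2, 8, 1], [2, 9, 1], [3, 10, 1], [3, 11, 1]
      ],
      "connecting_atoms": [0, 3],
      "charge": 0,
      "denticity": 2
    },
    {
      "index": 12,
      "name": "por",
      "full_name": "porphine (porphinato dianion)",
      "atoms": ["N", "C", "C", "C", "C", "N", "C", "C", "C", "C", "N", "C", "C", "C", "C", "N", "C", "C", "C", "C", "C", "C", "C", "C", "H", "H", "H", "H", "H", "H", "H", "H", "H", "H", "H", "H"],
      "bonds": [
        [0, 1, 1.5], [1, 2, 1.5], [2, 3, 1.5], [3, 4, 1.5], [4, 0, 1.5],
        [5, 6, 1.5], [6, 7, 1.5], [7, 8, 1.5], [8, 9, 1.5], [9, 5, 1.5],
        [10, 11, 1.5], [11, 12, 1.5], [12, 13, 1.5], [13, 14, 1.5], [14, 10, 1.5],
        [15, 16, 1.5], [16, 17, 1.5], [17, 18, 1.5], [18, 19, 1.5], [19, 15, 1.5],
        [4, 20, 1.5], [20, 6, 1.5],
        [9, 21, 1.5], [21, 11, 1.5],
        [14, 22, 1.5], [22, 16, 1.5],
        [19, 23, 1.5], [23, 1, 1.5],
        [2, 24, 1], [3, 25, 1], [7, 26, 1], [8, 27, 1], [12, 28, 1], [13, 29, 1], [17, 30, 1], [18, 31, 1],
        [20, 32, 1], [21, 33, 1], [22, 34, 1], [23, 35, 1]
      ],
      "connecting_atoms": [0, 5, 10, 15],
      "charge": -2,
      "denticity": 4
    },
    {
      "index": 13,
      "name": "H2O",
      "full_name": "water",
      "atoms": ["O", "H", "H"],
      "bonds": [[0, 1, 1], [0, 2, 1]],
      "connecting_atoms": [0],
      "charge": 0,
      "denticity": 1
    },
    {
      "index": 14,
      "name": "acac",
      "full_name": "acetylacetonate",
      "atoms": ["C", "C", "O", "C", "C", "O", "C", "H", "H", "H", "H", "H", "H", "H"],
      "bonds": [
        [0, 1, 1], [1, 2, 1.5], [1, 3, 1.5], [3, 4, 1.5], [4, 5, 1.5], [4, 6, 1],
        [0, 7, 1], [0, 8, 1], [0, 9, 1], [3, 10, 1], [6, 11, 1], [6, 12, 1], [6, 13, 1]
      ],
      "connecting_atoms": [2, 5],
      "charge": -1,
      "denticity": 2
    },
    {
      "index": 15,
      "name": "cat",
      "full_name": "catecholate",
      "atoms": ["C", "C", "C", "C", "C", "C", "O", "O", "H", "H", "H", "H"],
      "bonds": [
        [0, 1, 1.5], [1, 2, 1.5], [2, 3, 1.5], [3, 4, 1.5], [4, 5, 1.5], [5, 0, 1.5],
        [0, 6, 1], [1, 7, 1],
        [2, 8, 1], [3, 9, 1], [4, 10, 1], [5, 11, 1]
      ],
      "connecting_atoms": [6, 7],
      "charge": -2,
      "denticity": 2
    },
    {
      "index": 16,
      "name": "ox",
      "full_name": "oxalate",
      "atoms": ["C", "C", "O", "O", "O", "O"],
      "bonds": [[0, 1, 1], [0, 2, 1.5], [0, 3, 1.5], [1, 4, 1.5], [1, 5, 1.5]],
      "connecting_atoms": [2, 4],
      "charge": -2,
      "denticity": 2
    }
  ]
}
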