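{
 "metabolites": [
  "Orn",
  "akG",
  "Glu",
  "Gln",
  "P5c",
  "Pro"
 ],
 "externals": [
  "Arg",
  "urea",
  "NH4",
  "NAD",
  "NADH",
  "NADP",
  "NADPH",
  "ATP",
  "ADP",
  "Pi"
 ],
 "reactions": [
  {
   "id": "ARG",
   "substrates": [
    {
     "species": "Arg",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "Orn",
     "n": 1
    },
    {
     "species": "urea",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": ""
  },
  {
   "id": "OAT",
   "substrates": [
    {
     "species": "Orn",
     "n": 1
    },
    {
     "species": "akG",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "Glu",
     "n": 1
    },
    {
     "species": "P5c",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": ""
  },
  {
   "id": "GDH",
   "substrates": [
    {
     "species": "akG",
     "n": 1
    },
    {
     "species": "NH4",
     "n": 1
    },
    {
     "species": "NADH",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "Glu",
     "n": 1
    },
    {
     "species": "NAD",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": "stored akG -> Glu (glutamate-producing direction); the source stoichiometry table prints the opposite sign"
  },
  {
   "id": "GOGAT",
   "substrates": [
    {
     "species": "akG",
     "n": 1
    },
    {
     "species": "Gln",
     "n": 1
    },
    {
     "species": "NADPH",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "Glu",
     "n": 2
    },
    {
     "species": "NADP",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": ""
  },
  {
   "id": "GS",
   "substrates": [
    {
     "species": "Glu",
     "n": 1
    },
    {
     "species": "NH4",
     "n": 1
    },
    {
     "species": "ATP",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "Gln",
     "n": 1
    },
    {
     "species": "ADP",
     "n": 1
    },
    {
     "species": "Pi",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": ""
  },
  {
   "id": "P5CS",
   "substrates": [
    {
     "species": "Glu",
     "n": 1
    },
    {
     "species": "ATP",
     "n": 1
    },
    {
     "species": "NADPH",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "P5c",
     "n": 1
    },
    {
     "species": "ADP",
     "n": 1
    },
    {
     "species": "Pi",
     "n": 1
    },
    {
     "species": "NADP",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": ""
  },
  {
   "id": "P5CR",
   "substrates": [
    {
     "species": "P5c",
     "n": 1
    },
    {
     "species": "NADPH",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "Pro",
     "n": 1
    },
    {
     "species": "NADP",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": "stored P5c -> Pro (proline-producing direction); the source stoichiometry table prints the opposite sign"
  },
  {
   "id": "PRODH",
   "substrates": [
    {
     "species": "Pro",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "P5c",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": ""
  },
  {
   "id": "PROCO",
   "substrates": [
    {
     "species": "Pro",
     "n": 1
    }
   ],
   "products": [],
   "kind": "boundary",
   "orientation_note": ""
  },
  {
   "id": "AKGPR",
   "substrates": [],
   "products": [
    {
     "species": "akG",
     "n": 1
    }
   ],
   "kind": "boundary",
   "orientation_note": ""
  },
  {
   "id": "GLUPR",
   "substrates": [],
   "products": [
    {
     "species": "Glu",
     "n": 1
    }
   ],
   "kind": "boundary",
   "orientation_note": ""
  },
  {
   "id": "P5CDH",
   "substrates": [
    {
     "species": "P5c",
     "n": 1
    },
    {
     "species": "NAD",
     "n": 1
    }
   ],
   "products": [
    {
     "species": "Glu",
     "n": 1
    },
    {
     "species": "NADH",
     "n": 1
    }
   ],
   "kind": "enzymatic",
   "orientation_note": ""
  }
 ]
}
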