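{
  "comment": "Registered token tables for short-name parsing. Prefix tokens are matched greedily left-to-right (longest first) and may carry a comma-separated locant list; the site template's {n} is filled with each locant. Cores are matched against the whole name first (exact registry), then as the tail of the name before an optional suffix.",
  "prefixes": {
    "m":    {"kind": "methylation",               "site": "N{n}"},
    "s":    {"kind": "thiolation",                "site": "C{n}"},
    "se":   {"kind": "selenation",                "site": "C{n}"},
    "ges":  {"kind": "geranylthiolation",         "site": "C{n}"},
    "ac":   {"kind": "acetylation",               "site": "N{n}"},
    "acp":  {"kind": "aminocarboxypropylation",   "site": "N{n}"},
    "f":    {"kind": "formylation",               "site": "{n}"},
    "g":    {"kind": "glycinylcarbamoylation",    "site": "N{n}"},
    "hm":   {"kind": "hydroxymethylation",        "site": "{n}"},
    "ho":   {"kind": "hydroxylation",             "site": "C{n}"},
    "hn":   {"kind": "complex",                   "site": "N{n}",
             "notes": "hydroxynorvalylcarbamoyl"},
    "ht":   {"kind": "complex",                   "site": "N{n}",
             "notes": "hydroxy-threonylcarbamoyl"},
    "i":    {"kind": "isopentenylation",          "site": "N{n}"},
    "io":   {"kind": "complex",                   "site": "N{n}",
             "notes": "cis-hydroxyisopentenyl"},
    "inm":  {"kind": "aminomethyl-side-chain",    "site": "C{n}",
             "notes": "isopentenylaminomethyl"},
    "mo":   {"kind": "methoxylation",             "site": "C{n}"},
    "cm":   {"kind": "carboxymethyl-side-chain",  "site": "C{n}"},
    "chm":  {"kind": "carboxymethyl-side-chain",  "site": "C{n}",
             "notes": "carboxyhydroxymethyl"},
    "cmo":  {"kind": "carboxymethyl-side-chain",  "site": "C{n}",
             "notes": "oxyacetic acid"},
    "mcm":  {"kind": "carboxymethyl-side-chain",  "site": "C{n}",
             "notes": "methoxycarbonylmethyl (methyl ester of cm)"},
    "mchm": {"kind": "carboxymethyl-side-chain",  "site": "C{n}",
             "notes": "carboxyhydroxymethyl methyl ester"},
    "mcmo": {"kind": "carboxymethyl-side-chain",  "site": "C{n}",
             "notes": "oxyacetic acid methyl ester"},
    "ncm":  {"kind": "carbamoylmethyl-side-chain", "site": "C{n}"},
    "nchm": {"kind": "carbamoylmethyl-side-chain", "site": "C{n}",
             "notes": "carbamoylhydroxymethyl"},
    "cmnm": {"kind": "aminomethyl-side-chain",    "site": "C{n}",
             "notes": "carboxymethylaminomethyl"},
    "mnm":  {"kind": "aminomethyl-side-chain",    "site": "C{n}",
             "notes": "methylaminomethyl"},
    "nm":   {"kind": "aminomethyl-side-chain",    "site": "C{n}"},
    "tm":   {"kind": "taurinomethyl-side-chain",  "site": "C{n}"},
    "t":    {"kind": "threonylcarbamoylation",    "site": "N{n}"},
    "ct":   {"kind": "threonylcarbamoylation",    "site": "N{n}",
             "notes": "cyclic"},
    "ms":   {"kind": "complex",                   "site": "C{n}",
             "notes": "methylthio"},
    "msms": {"kind": "complex",                   "site": "C{n}",
             "notes": "methylthiomethylenethio"},
    "k":    {"kind": "lysidination",              "site": "C{n}"}
  },
  "cores": {
    "A": {"root": "A"},
    "C": {"root": "C"},
    "G": {"root": "G"},
    "U": {"root": "U"},
    "I": {"root": "A", "ops": [{"kind": "deamination", "site": ""}]},
    "Ψ": {"root": "U", "ops": [{"kind": "isomerization", "site": ""}]},
    "D": {"root": "U", "ops": [{"kind": "reduction", "site": ""}]},
    "C+": {"root": "C", "ops": [{"kind": "agmatination", "site": ""}]},
    "k2C": {"root": "C", "ops": [{"kind": "lysidination", "site": "C2"}]},
    "Q": {"root": "G", "atomic": true, "notes": "queuosine"},
    "G+": {"root": "G", "atomic": true, "notes": "archaeosine"},
    "preQ0": {"root": "G", "atomic": true},
    "preQ1": {"root": "G", "atomic": true},
    "oQ": {"root": "G", "atomic": true, "notes": "epoxyqueuosine"},
    "galQ": {"root": "G", "atomic": true},
    "manQ": {"root": "G", "atomic": true},
    "gluQ": {"root": "G", "atomic": true},
    "imG-14": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "imG": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "imG2": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "mimG": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "yW": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "yW-58": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "yW-72": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "yW-86": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "o2yW": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "OHyW": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "OHyWx": {"root": "G", "atomic": true, "notes": "wyosine family"},
    "OHyWy": {"root": "G", "atomic": true, "notes": "wyosine family"}
  },
  "suffixes": {
    "m": {"kind": "2'-O-methylation", "site": "2'-O"},
    "r(p)": {"kind": "2'-O-ribosylation", "site": "2'-O"}
  },
  "aliases": {
    "psi": "Ψ",
    "psi-m": "Ψm",
    "m1psi": "m1Ψ",
    "m3psi": "m3Ψ",
    "acp3psi": "acp3Ψ",
    "m1acp3psi": "m1acp3Ψ"
  }
}
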