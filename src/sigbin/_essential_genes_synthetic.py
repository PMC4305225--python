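"""Synthetic stand-in universe of 107 single-copy essential-gene names.

Bin quality assessment scores completeness and contamination against a
reference collection of 107 bacterial single-copy marker genes. The exact
published gene list is not redistributed here; this module ships a
synthetic stand-in of the same size, drawn from the well-known core of
bacterial essential genes (ribosomal proteins, aminoacyl-tRNA
synthetases, translation factors, RNA polymerase subunits, replication
and secretion machinery). Only the universe SIZE matters for completeness
denominators; users with a real annotation pipeline should pass their own
gene universe.
"""

ESSENTIAL_GENES_SYNTHETIC: tuple[str, ...] = (
    # 50S ribosomal proteins
    "rplA", "rplB", "rplC", "rplD", "rplE", "rplF", "rplI", "rplJ", "rplK",
    "rplL", "rplM", "rplN", "rplO", "rplP", "rplQ", "rplR", "rplS", "rplT",
    "rplU", "rplV", "rplW", "rplX", "rplY",
    "rpmA", "rpmB", "rpmC", "rpmD", "rpmE", "rpmF", "rpmG", "rpmH", "rpmI",
    # 30S ribosomal proteins
    "rpsB", "rpsC", "rpsD", "rpsE", "rpsF", "rpsG", "rpsH", "rpsI", "rpsJ",
    "rpsK", "rpsL", "rpsM", "rpsN", "rpsO", "rpsP", "rpsQ", "rpsR", "rpsS",
    "rpsT",
    # aminoacyl-tRNA synthetases
    "alaS", "argS", "aspS", "cysS", "gltX", "glyS", "hisS", "ileS", "leuS",
    "lysS", "metG", "pheS", "pheT", "proS", "serS", "thrS", "trpS", "tyrS",
    "valS",
    # translation factors
    "fusA", "infA", "infB", "infC", "tsf", "prfA", "frr",
    # RNA polymerase core
    "rpoA", "rpoB", "rpoC",
    # replication
    "dnaA", "dnaB", "dnaG", "dnaN", "dnaX", "gyrA", "gyrB", "polA", "ligA",
    # secretion, GTPases, housekeeping
    "ffh", "ftsY", "secA", "secY", "secE", "yidC", "era", "engA", "obg",
    "lepA", "rnc", "pyrG", "nusA", "nusG", "pgk", "tpiA", "eno", "gapA",
)

assert len(ESSENTIAL_GENES_SYNTHETIC) == 107
assert len(set(ESSENTIAL_GENES_SYNTHETIC)) == 107
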