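"""Published segregation panels for the Tg(flk1:RFP)is18 zebrafish line.

The haplotype panel (10 transgenic / 10 non-transgenic siblings) and the
linkage panel (100 transgenic / 100 non-transgenic offspring of an
is18/+ female x WIK male outcross) are encoded from the published
per-marker genotype tallies.  The tallies are marginal per marker, so
individuals are assigned genotypes row-wise in order; haplotype
inference and recombinant counting depend only on those marginals.

Marker allele labels follow the PCR product-size convention:
L (long), M (middle), S (short).
"""

from __future__ import annotations

from .linkage import GenotypeTable, Genotype, Individual, Marker

# chromosome 3 positions (Zv9) of the scored markers; Z7486 is the
# unlinked control marker on the same chromosome
MARKERS = [
    Marker("Z7419", "chr3", 23158018),
    Marker("G39247", "chr3", 24163628),
    Marker("Z5197", "chr3", 24324461),
    Marker("cbx1a_STS", "chr3", 24360325),
    Marker("Z7486", "chr3", 59983229),
]

# is18/+ F5 female (transgenic parent) and WIK male
TRANSGENIC_PARENT: dict[str, Genotype] = {
    "Z7419": ("L", "M"),
    "G39247": ("L", "S"),
    "Z5197": ("L", "S"),
    "cbx1a_STS": ("L", "M"),
    "Z7486": ("L", "S"),
}
OTHER_PARENT: dict[str, Genotype] = {
    "Z7419": ("M", "S"),
    "G39247": ("L", "L"),
    "Z5197": ("S", "S"),
    "cbx1a_STS": ("M", "S"),
    "Z7486": ("L", "S"),
}

# published linked haplotype of the transgene chromosome
PUBLISHED_HAPLOTYPE = {
    "Z7419": "L",
    "G39247": "S",
    "Z5197": "L",
    "cbx1a_STS": "L",
}

# per-marker genotype tallies: (genotype, count) per phenotype class
_HAPLOTYPE_PANEL_TALLIES: dict[str, dict[bool, list[tuple[str, int]]]] = {
    "Z7419": {True: [("L/M", 6), ("L/S", 4)], False: [("M/M", 6), ("M/S", 4)]},
    "G39247": {True: [("L/S", 10)], False: [("L/L", 10)]},
    "Z5197": {True: [("L/S", 10)], False: [("S/S", 10)]},
    "cbx1a_STS": {True: [("L/M", 6), ("L/S", 4)], False: [("M/M", 6), ("M/S", 4)]},
    "Z7486": {
        True: [("L/L", 3), ("L/S", 4), ("S/S", 3)],
        False: [("L/L", 4), ("L/S", 2), ("S/S", 4)],
    },
}

# 100 + 100 offspring panel; markers not scored in a class are missing
_LINKAGE_PANEL_TALLIES: dict[str, dict[bool, list[tuple[str, int]]]] = {
    "Z7419": {True: [("L/M", 57), ("L/S", 42), ("M/M", 1)], False: []},
    "Z5197": {True: [("L/S", 100)], False: []},
}


def _expand(
    tallies: dict[str, dict[bool, list[tuple[str, int]]]],
    n_transgenic: int,
    n_nontransgenic: int,
    marker_ids: list[str],
) -> GenotypeTable:
    individuals = [
        Individual(f"tg_{i + 1:03d}", True) for i in range(n_transgenic)
    ] + [Individual(f"wt_{i + 1:03d}", False) for i in range(n_nontransgenic)]
    genotypes: dict[tuple[str, str], Genotype] = {}
    for mid in marker_ids:
        for transgenic in (True, False):
            inds = [i for i in individuals if i.transgenic == transgenic]
            row = 0
            for geno, count in tallies.get(mid, {}).get(transgenic, []):
                pair = tuple(sorted(geno.split("/")))
                for _ in range(count):
                    genotypes[(inds[row].id, mid)] = pair
                    row += 1
    markers = [m for m in MARKERS if m.id in marker_ids]
    return GenotypeTable(individuals=individuals, markers=markers, genotypes=genotypes)


def is18_haplotype_panel() -> GenotypeTable:
    """10 is18/+ and 10 +/+ siblings scored at all five markers."""
    return _expand(_HAPLOTYPE_PANEL_TALLIES, 10, 10, [m.id for m in MARKERS])


def is18_linkage_panel() -> GenotypeTable:
    """100 is18/+ and 100 +/+ outcross offspring (Z7419 and Z5197 scored
    in the transgenic class only)."""
    return _expand(_LINKAGE_PANEL_TALLIES, 100, 100, ["Z7419", "Z5197"])
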