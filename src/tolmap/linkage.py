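"""STR/STS linkage analysis of transgene co-segregation.

Given a sibling panel genotyped at PCR-sized microsatellite markers and
scored for the transgene (by reporter expression or junction PCR), this
module infers the marker haplotype of the transgene-bearing chromosome,
counts recombinant meioses per marker, and converts the recombination
fraction to genetic map distance (1 recombinant in 100 informative
meioses = 1 cM, the direct small-distance estimator).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from scipy import stats

UNINFORMATIVE = "UNINFORMATIVE"

Genotype = tuple[str, str]  # unordered allele-label pair, stored sorted


@dataclass
class Individual:
    id: str
    transgenic: bool


@dataclass
class Marker:
    id: str
    scaffold: str
    position: int


@dataclass
class GenotypeTable:
    """Marker genotypes for a sibling panel.

    ``genotypes`` maps (individual id, marker id) to a sorted allele pair;
    missing cells are simply absent.
    """

    individuals: list[Individual]
    markers: list[Marker]
    genotypes: dict[tuple[str, str], Genotype]

    def genotype(self, individual_id: str, marker_id: str) -> Genotype | None:
        return self.genotypes.get((individual_id, marker_id))


@dataclass
class HaplotypeCall:
    marker: str
    linked_allele: str  # allele label or UNINFORMATIVE
    n_consistent: int = 0
    n_total: int = 0


@dataclass
class LinkageResult:
    marker: str
    n_informative: int
    n_recombinant: int

    @property
    def r(self) -> float:
        return self.n_recombinant / self.n_informative

    @property
    def cM(self) -> float:
        return map_distance(self)


def _possible_transmissions(
    genotype: Genotype, parent: Genotype, other_parent: Genotype
) -> set[str]:
    """Alleles the ``parent`` could have transmitted to produce
    ``genotype``, given the other parent's genotype."""
    out = set()
    a, b = genotype
    for x in set(parent):
        if x == a and b in other_parent:
            out.add(x)
        if x == b and a in other_parent:
            out.add(x)
    return out


def infer_linked_haplotype(
    table: GenotypeTable,
    transgenic_parent_genotype: dict[str, Genotype],
    other_parent_genotype: dict[str, Genotype],
) -> list[HaplotypeCall]:
    """Infer the transgene-linked allele at each marker.

    The linked allele is the transgenic-parent allele that every
    transgenic sibling could have received from that parent and that no
    non-transgenic sibling could have; when no (or more than one) allele
    separates the phenotype classes, the marker is UNINFORMATIVE —
    e.g. when both parents share the same heterozygous genotype.
    """
    if not table.individuals:
        raise ValueError("empty sibling panel")
    calls = []
    for marker in table.markers:
        mid = marker.id
        if mid not in transgenic_parent_genotype or mid not in other_parent_genotype:
            raise ValueError(f"marker {mid!r} absent from parental genotypes")
        p_tg = tuple(sorted(transgenic_parent_genotype[mid]))
        p_other = tuple(sorted(other_parent_genotype[mid]))
        scored = [
            (ind, table.genotype(ind.id, mid))
            for ind in table.individuals
            if table.genotype(ind.id, mid) is not None
        ]
        candidates = []
        for allele in sorted(set(p_tg)):
            ok = True
            for ind, g in scored:
                trans = _possible_transmissions(g, p_tg, p_other)
                if ind.transgenic and allele not in trans:
                    ok = False
                    break
                if not ind.transgenic and allele in trans:
                    ok = False
                    break
            if ok:
                candidates.append(allele)
        if len(candidates) == 1:
            linked = candidates[0]
            n_consistent = 0
            for ind, g in scored:
                trans = _possible_transmissions(g, p_tg, p_other)
                if ind.transgenic == (linked in trans):
                    n_consistent += 1
            calls.append(HaplotypeCall(mid, linked, n_consistent, len(scored)))
        else:
            calls.append(HaplotypeCall(mid, UNINFORMATIVE, 0, len(scored)))
    return calls


def count_recombinants(
    table: GenotypeTable,
    haplotype: list[HaplotypeCall],
    transgenic_parent_genotype: dict[str, Genotype],
    other_parent_genotype: dict[str, Genotype],
) -> list[LinkageResult]:
    """Count recombinant meioses per marker against the linked haplotype.

    An offspring is recombinant iff it is transgenic yet the transgenic
    parent's transmitted allele is not the linked one, or non-transgenic
    yet carries the linked allele from that parent.  Offspring whose
    transmitted allele cannot be attributed unambiguously, and missing
    genotypes, are excluded from the informative count.  UNINFORMATIVE
    markers are skipped.
    """
    results = []
    for call in haplotype:
        if call.linked_allele == UNINFORMATIVE:
            continue
        mid = call.marker
        p_tg = tuple(sorted(transgenic_parent_genotype[mid]))
        p_other = tuple(sorted(other_parent_genotype[mid]))
        n_informative = 0
        n_recombinant = 0
        for ind in table.individuals:
            g = table.genotype(ind.id, mid)
            if g is None:
                continue
            trans = _possible_transmissions(g, p_tg, p_other)
            if len(trans) != 1:
                continue  # ambiguous or incompatible attribution
            carried = call.linked_allele in trans
            n_informative += 1
            if ind.transgenic != carried:
                n_recombinant += 1
        results.append(LinkageResult(mid, n_informative, n_recombinant))
    return results


def map_distance(res: LinkageResult) -> float:
    """Map distance in centimorgans: 100 x recombination fraction."""
    if res.n_informative == 0:
        raise ValueError(f"no informative meioses for marker {res.marker}")
    return 100.0 * res.n_recombinant / res.n_informative


def mendelian_ratio_test(n_transgenic: int, n_nontransgenic: int) -> dict[str, float]:
    """Exact two-sided binomial test of 1:1 transgene transmission."""
    n = n_transgenic + n_nontransgenic
    if n <= 0:
        raise ValueError("totals must be > 0")
    test = stats.binomtest(n_transgenic, n, p=0.5, alternative="two-sided")
    return {"statistic": n_transgenic / n, "p": test.pvalue}


# ---------------------------------------------------------------------------
# Tab-delimited I/O
# ---------------------------------------------------------------------------

MISSING = "NA"


def write_genotype_table(table: GenotypeTable, path: str | os.PathLike) -> None:
    """Header of marker ids; one row per individual:
    id, phenotype (1/0), slash-separated allele pairs, NA for missing."""
    marker_ids = [m.id for m in table.markers]
    with open(path, "w") as fh:
        fh.write("individual\tphenotype\t" + "\t".join(marker_ids) + "\n")
        for ind in table.individuals:
            cells = []
            for mid in marker_ids:
                g = table.genotype(ind.id, mid)
                cells.append(MISSING if g is None else "/".join(g))
            fh.write(f"{ind.id}\t{int(ind.transgenic)}\t" + "\t".join(cells) + "\n")


def read_genotype_table(path: str | os.PathLike) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        marker_ids = header[2:]
        individuals = []
        genotypes: dict[tuple[str, str], Genotype] = {}
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            ind = Individual(cells[0], cells[1] in ("1", "+"))
            individuals.append(ind)
            for mid, cell in zip(marker_ids, cells[2:]):
                if cell == MISSING:
                    continue
                alleles = cell.split("/")
                if len(alleles) != 2:
                    raise ValueError(f"malformed genotype cell {cell!r}")
                genotypes[(ind.id, mid)] = tuple(sorted(alleles))
    return GenotypeTable(
        individuals=individuals,
        markers=[Marker(mid, "", 0) for mid in marker_ids],
        genotypes=genotypes,
    )


def write_parent_genotypes(
    transgenic_parent: dict[str, Genotype],
    other_parent: dict[str, Genotype],
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        fh.write("marker\ttransgenic_parent\tother_parent\n")
        for mid in transgenic_parent:
            fh.write(
                f"{mid}\t{'/'.join(transgenic_parent[mid])}\t"
                f"{'/'.join(other_parent[mid])}\n"
            )


def read_parent_genotypes(
    path: str | os.PathLike,
) -> tuple[dict[str, Genotype], dict[str, Genotype]]:
    tg: dict[str, Genotype] = {}
    other: dict[str, Genotype] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            mid, g1, g2 = line.rstrip("\n").split("\t")
            tg[mid] = tuple(sorted(g1.split("/")))
            other[mid] = tuple(sorted(g2.split("/")))
    return tg, other


def linkage_report(
    haplotype: list[HaplotypeCall], results: list[LinkageResult]
) -> str:
    """Per-marker summary mirroring the published table layout."""
    by_marker = {r.marker: r for r in results}
    lines = ["marker\tlinked_allele\tconsistent\tinformative\trecombinants\tcM"]
    for call in haplotype:
        r = by_marker.get(call.marker)
        if call.linked_allele == UNINFORMATIVE or r is None:
            lines.append(
                f"{call.marker}\t{call.linked_allele}\t{call.n_consistent}/"
                f"{call.n_total}\tNA\tNA\tNA"
            )
        else:
            cm = "NA" if r.n_informative == 0 else f"{r.cM:.2f}"
            lines.append(
                f"{call.marker}\t{call.linked_allele}\t{call.n_consistent}/"
                f"{call.n_total}\t{r.n_informative}\t{r.n_recombinant}\t{cm}"
            )
    return "\n".join(lines) + "\n"
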