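"""Gene neighborhoods around rdhA-like anchors and the regulator-domain census.

A neighborhood is the set of protein-coding genes fewer than five gene-order
positions away from the anchor on each side (<= 4 per side), regardless of
strand or intergenic distance, wrapping around circular genomes. Members
count toward a regulator category when they carry at least one signaling
domain of that category at a domain e-value below the cutoff (default
0.001). The category map is configuration, not code: signaling-domain lists
evolve, so the defaults ship as editable data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genomeio import DomainHit, GenomeRecord

log = logging.getLogger(__name__)

#: Default regulator-category map (editable; see load_category_map).
DEFAULT_CATEGORY_MAP: dict[str, tuple[str, ...]] = {
    "CrpFnr": ("cNMP_binding", "HTH_Crp_2"),
    "HK_RR": ("HisKA", "ATPase_c", "Response_reg", "Trans_reg_C", "PAS"),
    "MarR": ("MarR_2",),
    # any further domain here counts as OtherRegulatory
    "OtherRegulatory": ("GerE", "HTH_1", "HTH_3", "Sigma54_activat", "GAF", "SpoIIE"),
}


@dataclass
class NeighborhoodCensus:
    anchor: str
    members: list[str]
    domain_hits: dict[str, list[DomainHit]]
    category_counts: dict[str, int]
    multi_category_members: list[str] = field(default_factory=list)


def load_category_map(path: str) -> dict[str, tuple[str, ...]]:
    """Read a category map from simple YAML (category: [domain, ...])."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: tuple(v) for k, v in raw.items()}


def write_category_map(cmap: dict, path: str) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in cmap.items()}, fh, sort_keys=True)


def extract_neighborhood(anchor: str, genome: GenomeRecord, radius: int = 5):
    """Protein-coding genes strictly fewer than ``radius`` gene-order
    positions from the anchor on each side (anchor excluded).

    Returns (upstream, downstream) lists of locus_tags in genome order;
    circular topology wraps. RNA genes between CDSs do not consume a
    position. The anchor must itself be a CDS feature.
    """
    cds = [f.locus_tag for f in genome.features if f.ftype == "CDS"]
    try:
        idx = cds.index(anchor)
    except ValueError:
        raise KeyError(f"anchor {anchor!r} is not a CDS of genome {genome.id}")
    span = radius - 1
    n = len(cds)
    if genome.topology == "circular" and n > 2 * span:
        upstream = [cds[(idx - d) % n] for d in range(span, 0, -1)]
        downstream = [cds[(idx + d) % n] for d in range(1, span + 1)]
    else:
        upstream = cds[max(0, idx - span):idx]
        downstream = cds[idx + 1:idx + 1 + span]
    return upstream, downstream


def census(members: list[str], domain_hits: list[DomainHit],
           evalue_cutoff: float = 0.001,
           category_map: dict | None = None,
           anchor: str = "") -> NeighborhoodCensus:
    """Count members per regulator category from their qualifying domains.

    A member counts toward a category when it carries >= 1 domain of that
    category with e-value strictly below the cutoff; a member with domains
    from several categories increments each (logged). Domains absent from
    the configured map are ignored.
    """
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    by_member: dict[str, list[DomainHit]] = {m: [] for m in members}
    for h in domain_hits:
        if h.locus_tag in by_member and h.evalue < evalue_cutoff:
            by_member[h.locus_tag].append(h)
    counts = {cat: 0 for cat in cmap}
    multi = []
    for m in members:
        cats = {cat for cat, doms in cmap.items()
                for h in by_member[m] if h.domain_name in doms}
        for cat in cats:
            counts[cat] += 1
        if len(cats) > 1:
            multi.append(m)
            log.info("member %s counted in multiple categories: %s", m, sorted(cats))
    return NeighborhoodCensus(anchor, list(members), by_member, counts, multi)


def census_around(anchor: str, genome: GenomeRecord, domain_hits: list[DomainHit],
                  radius: int = 5, evalue_cutoff: float = 0.001,
                  category_map: dict | None = None) -> NeighborhoodCensus:
    up, down = extract_neighborhood(anchor, genome, radius)
    return census(up + down, domain_hits, evalue_cutoff, category_map, anchor=anchor)


def compare_groups(censuses: list[NeighborhoodCensus], group_labels: list[str]):
    """Group x category count table (plus per-row fractions).

    Counts are summed per group; the result is invariant under census order.
    """
    import pandas as pd

    if len(censuses) != len(group_labels):
        raise ValueError("one group label per census required")
    cats = sorted({c for cen in censuses for c in cen.category_counts})
    rows = {}
    for g in sorted(set(group_labels)):
        rows[g] = {c: 0 for c in cats}
    for cen, g in zip(censuses, group_labels):
        for c, v in cen.category_counts.items():
            rows[g][c] += v
    table = pd.DataFrame(rows).T[cats]
    totals = table.sum(axis=1)
    for c in cats:
        table[f"frac_{c}"] = (table[c] / totals.replace(0, 1)).round(4)
    return table


def write_census_tsv(censuses: list[NeighborhoodCensus], path: str) -> None:
    cats = sorted({c for cen in censuses for c in cen.category_counts})
    with open(path, "w") as fh:
        fh.write("anchor\tn_members\t" + "\t".join(cats) + "\tmulti_category\n")
        for cen in censuses:
            fh.write(f"{cen.anchor}\t{len(cen.members)}\t"
                     + "\t".join(str(cen.category_counts.get(c, 0)) for c in cats)
                     + "\t" + ",".join(cen.multi_category_members) + "\n")
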