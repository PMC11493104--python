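"""Synthetic invasion-genetics datasets with machine-readable truth.

The generator emulates the statistical structure of an mtDNA invasion
study:

* several divergent *native* regional haplotype pools, each descending from
  a region ancestor carrying its own block of private substitutions, so
  regions are separated by long mutational branches;
* *introduced* populations that underwent a founder bottleneck: they draw
  almost exclusively from a small set of haplotypes exported from one source
  region, dominated by a single haplotype, plus rare new one-step
  derivatives;
* an optional distant *outgroup* record emulating a sister species.

Mutations are placed at globally unique sites (infinite-sites
approximation), so the Hamming distance between any two simulated sequences
equals the number of mutation events separating them — truth distances are
exact for oracle tests.  Within-region haplotype frequencies follow a
geometric series (one common haplotype plus progressively rarer ones),
reproducing the skew typical of field samples.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundsError, CapacityError
from .seqio import Alignment, SpecimenTable, write_alignment, write_specimen_table

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_HOSTS = ("potato", "tomato", "celery", "lettuce", "beans", "flower")


@dataclass
class SimConfig:
    """Parameters of the invasion simulation.

    Defaults describe a three-region native range whose source region exports
    four haplotypes; introduced populations carry the top exported haplotype
    at ~90% frequency.  ``seed`` is mandatory.
    """

    seed: int
    L: int = 2181
    n_regions: int = 3
    between_region_steps: int = 12
    within_region_haps: tuple[int, int] = (5, 19)
    n_per_native_pop: tuple[int, ...] = (20, 20, 20)
    n_per_introduced_pop: tuple[int, ...] = (30, 20, 10)
    n_invasive_haps: int = 4
    dominance: float = 0.9
    singleton_rate: float = 0.03
    geometric_ratio: float = 0.5
    outgroup_divergence: float = 0.056
    include_outgroup: bool = True
    source_region: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dominance <= 1:
            raise BoundsError("dominance must be in (0, 1]")
        if not 0 <= self.singleton_rate < 1:
            raise BoundsError("singleton_rate must be in [0, 1)")
        if self.between_region_steps < 1:
            raise BoundsError("between_region_steps must be >= 1")
        if self.n_regions < 1:
            raise BoundsError("need at least one native region")
        if self.L < self.between_region_steps * self.n_regions:
            raise CapacityError(
                "sequence too short for the requested between-region divergence"
            )
        if len(self.n_per_native_pop) != self.n_regions:
            raise BoundsError(
                "n_per_native_pop must give one population size per region"
            )
        lo, hi = self.within_region_haps
        if not 1 <= lo <= hi:
            raise BoundsError("within_region_haps must be a range 1 <= lo <= hi")
        if not 1 <= self.n_invasive_haps <= lo:
            raise BoundsError(
                "n_invasive_haps must be between 1 and the minimum pool size"
            )
        if not 0 <= self.source_region < self.n_regions:
            raise BoundsError("source_region out of range")
        if not 0 < self.geometric_ratio < 1:
            raise BoundsError("geometric_ratio must be in (0, 1)")


@dataclass
class SimResult:
    """Simulated alignment, metadata, truth table and generating sequences."""

    alignment: Alignment
    specimens: SpecimenTable
    truth: pd.DataFrame
    hap_seqs: dict[str, str]
    exported_haps: list[str]
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write ``alignment.fasta``, ``specimens.tsv`` and ``truth.tsv``.

        Output is byte-identical across runs with the same config.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": outdir / "alignment.fasta",
            "specimens": outdir / "specimens.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_alignment(self.alignment, paths["alignment"])
        write_specimen_table(self.specimens, paths["specimens"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


class _SitePool:
    """Hands out globally unique mutable sites (infinite-sites model)."""

    def __init__(self, L: int, rng: np.random.Generator) -> None:
        self.sites = rng.permutation(L)
        self.used = 0

    def take(self, k: int) -> np.ndarray:
        if self.used + k > len(self.sites):
            raise CapacityError(
                f"simulation needs more than {len(self.sites)} mutable sites; "
                "increase L or reduce divergence parameters"
            )
        out = self.sites[self.used : self.used + k]
        self.used += k
        return out


def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    # shift by 1-3 in base space: always a different base
    out[sites] = (out[sites] + rng.integers(1, 4, size=len(sites))) % 4
    return out


def _geometric_weights(k: int, ratio: float) -> np.ndarray:
    w = ratio ** np.arange(k)
    return w / w.sum()


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate an alignment, specimen table and truth table from ``config``.

    Native populations sample their region's haplotype pool with geometric
    frequencies.  Introduced populations sample the exported set: the top
    exported haplotype with probability ``dominance``, the rest geometrically;
    each non-seeded introduced specimen may instead carry a brand-new one-step
    derivative with probability ``singleton_rate``.  To guarantee that every
    exported haplotype is observable as invasive, one carrier of each is
    seeded deterministically into the source-region native population and
    into the first introduced population (the study analog: every exported
    haplotype established at least once).
    """
    rng = np.random.default_rng(config.seed)
    pool = _SitePool(config.L, rng)
    root = rng.integers(0, 4, size=config.L)

    # Regional haplotype pools, each a random mutation tree off its ancestor.
    # Tree depth is capped below half the between-region divergence so that,
    # with the ancestor always sampled, every region stays connected by
    # branches shorter than the cluster cut (between_region_steps / 2).
    lo, hi = config.within_region_haps
    max_depth = max(config.between_region_steps // 2 - 1, 1)
    region_pools: list[list[str]] = []
    hap_arr: dict[str, np.ndarray] = {}
    hap_region: dict[str, int] = {}
    for r in range(config.n_regions):
        ancestor = _mutate(root, pool.take(config.between_region_steps), rng)
        n_haps = int(rng.integers(lo, hi + 1))
        ids = [f"R{r + 1}.H{t + 1:02d}" for t in range(n_haps)]
        hap_arr[ids[0]] = ancestor
        depth = {ids[0]: 0}
        for t in range(1, n_haps):
            shallow = [h for h in ids[:t] if depth[h] < max_depth]
            parent = shallow[int(rng.integers(0, len(shallow)))]
            steps = int(rng.integers(1, 1 + min(3, max_depth - depth[parent])))
            hap_arr[ids[t]] = _mutate(hap_arr[parent], pool.take(steps), rng)
            depth[ids[t]] = depth[parent] + steps
        for hid in ids:
            hap_region[hid] = r + 1
        region_pools.append(ids)

    exported = region_pools[config.source_region][: config.n_invasive_haps]
    export_weights = _geometric_weights(
        max(len(exported) - 1, 1), config.geometric_ratio
    )

    ids: list[str] = []
    seq_of: list[str] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    singleton_n = 0

    def emit(country: str, status: str, hap_id: str, region, pathway: str) -> None:
        i = sum(1 for row in meta_rows if row["country"] == country) + 1
        sid = f"{country}-{i:03d}"
        ids.append(sid)
        seq_of.append(hap_id)
        meta_rows.append(
            {
                "specimen_id": sid,
                "country": country,
                "location": f"{country}-1",
                "status": status,
                "host": _HOSTS[int(rng.integers(0, len(_HOSTS)))],
                "year": str(1998 + int(rng.integers(0, 6))),
            }
        )
        truth_rows.append(
            {
                "specimen_id": sid,
                "true_haplotype": hap_id,
                "region": region,
                "pathway": pathway,
            }
        )

    # native populations: one per region; the regional ancestor (and, in the
    # source region, every exported haplotype) is always represented
    for r, size in enumerate(config.n_per_native_pop):
        country = f"NAT{r + 1}"
        pool_ids = region_pools[r]
        weights = _geometric_weights(len(pool_ids), config.geometric_ratio)
        seeded = exported if r == config.source_region else [pool_ids[0]]
        for hap_id in seeded[:size]:
            emit(country, "native", hap_id, r + 1, "native")
        for _ in range(size - min(len(seeded), size)):
            hap_id = pool_ids[int(rng.choice(len(pool_ids), p=weights))]
            emit(country, "native", hap_id, r + 1, "native")

    # introduced populations: bottlenecked draws from the exported set
    src = config.source_region + 1
    for k, size in enumerate(config.n_per_introduced_pop):
        country = f"INT{k + 1}"
        seeded = exported if k == 0 else []
        for hap_id in seeded[:size]:
            emit(country, "introduced", hap_id, src, "exported")
        for _ in range(size - min(len(seeded), size)):
            if len(exported) > 1 and rng.random() >= config.dominance:
                j = 1 + int(rng.choice(len(exported) - 1, p=export_weights))
            else:
                j = 0
            hap_id = exported[j]
            if rng.random() < config.singleton_rate:
                singleton_n += 1
                new_id = f"{hap_id}+s{singleton_n:02d}"
                hap_arr[new_id] = _mutate(hap_arr[hap_id], pool.take(1), rng)
                hap_region[new_id] = src
                emit(country, "introduced", new_id, src, "singleton-derivative")
            else:
                emit(country, "introduced", hap_id, src, "exported")

    if config.include_outgroup:
        steps = round(config.outgroup_divergence * config.L)
        hap_arr["OUTGROUP"] = _mutate(root, pool.take(steps), rng)
        hap_region["OUTGROUP"] = 0
        emit("Langei", "outgroup", "OUTGROUP", "", "outgroup")

    decode = np.array(list("ACGT"))
    hap_seqs = {hid: "".join(decode[arr]) for hid, arr in hap_arr.items()}
    alignment = Alignment(ids, [hap_seqs[h] for h in seq_of])
    specimens = SpecimenTable(pd.DataFrame(meta_rows))
    truth = pd.DataFrame(truth_rows)
    return SimResult(alignment, specimens, truth, hap_seqs, list(exported), config)


def alignment_from_counts(
    tables: dict[str, dict[str, int]],
    status_by_group: dict[str, str],
    L: int = 2181,
    steps: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[Alignment, SpecimenTable]:
    """Construct a dataset realizing printed haplotype frequency tables.

    ``tables`` maps group (country) -> haplotype id -> carrier count; the
    same haplotype id in two groups denotes the same sequence, so shared and
    private haplotypes can be laid out exactly as in a published frequency
    table.  Each haplotype id receives ``steps[id]`` private substitutions
    (default 1) at globally unique sites relative to a common root, so the
    distance between two haplotypes is ``steps[a] + steps[b]``.  A ``steps``
    of 0 makes that haplotype the root itself (at most one id may use it).

    Returns an alignment plus matching metadata with one location per group.
    """
    rng = np.random.default_rng(seed)
    pool = _SitePool(L, rng)
    root = rng.integers(0, 4, size=L)
    steps = steps or {}
    hap_ids = sorted({h for table in tables.values() for h in table})
    decode = np.array(list("ACGT"))
    hap_seq: dict[str, str] = {}
    for hid in hap_ids:
        k = steps.get(hid, 1)
        arr = _mutate(root, pool.take(k), rng) if k else root
        hap_seq[hid] = "".join(decode[arr])

    ids: list[str] = []
    seqs: list[str] = []
    rows: list[dict] = []
    for group, table in tables.items():
        i = 0
        for hid, count in table.items():
            for _ in range(count):
                i += 1
                sid = f"{group}-{i:03d}"
                ids.append(sid)
                seqs.append(hap_seq[hid])
                rows.append(
                    {
                        "specimen_id": sid,
                        "country": group,
                        "location": f"{group}-1",
                        "status": status_by_group[group],
                        "host": "",
                        "year": "",
                    }
                )
    return Alignment(ids, seqs), SpecimenTable(pd.DataFrame(rows))
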