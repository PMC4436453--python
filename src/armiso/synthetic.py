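"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's three input classes:

* :func:`generate_phylo_families` — per-species hairpin/mature FASTA with a
  conserved 5p arm and a faster-evolving 3p arm (i.i.d. per-position
  substitutions at arm-specific rates, a faster background rate outside the
  arms, loop-only indels and terminal-length jitter), emulating the
  cross-species conservation structure of real miRNA families.
* :func:`generate_isomir_readsets` — per-sample collapsed read sets whose
  isomiR proportions are Dirichlet-multinomial around a template dominated by
  the canonical sequence, with 5'/3' end offsets, non-template 3' additions
  and a condition-specific concentration (smaller = more dispersed, the
  disease signature).
* :func:`generate_utrs` — random UTRs with seed-complement sites planted at a
  controlled rate for target-scan recovery tests.

Every generator is fully deterministic given (config, seed) and writes a
truth table alongside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .mirbase_io import HairpinRecord, MatureRecord, write_fasta
from .isomir import ReadSet
from .targets import SeedSequence, reverse_complement

NUCLEOTIDES = np.array(list("ACGU"))


@dataclass
class SyntheticConfig:
    """All generator parameters; defaults are the package's study conditions."""

    seed: int = 0
    # phylogenetic families
    n_species: int = 10
    n_families: int = 40
    n_partial_families: int = 0  # families planted in only a subset of species
    hairpin_length: int = 82
    mature_length_mean: float = 22.0
    mature_length_sd: float = 1.0
    mature_length_bounds: tuple[int, int] = (20, 24)
    sub_rate_5p: float = 0.02
    sub_rate_3p: float = 0.12
    background_rate: float | None = None  # default: 1.5 x max(arm rates)
    indel_rate: float = 0.01  # loop-region deletions only
    terminal_jitter_max: int = 2
    # isomiR read sets
    n_samples_disease: int = 20
    n_samples_control: int = 20
    dominant_fraction: float = 70.0  # percent of locus reads on the canonical isomiR
    offset_max: int = 2  # offsets drawn from [-offset_max..offset_max]^2
    tail_probability: float = 0.1
    max_tail_length: int = 3
    dispersion_control: float = 50.0
    dispersion_disease: float = 12.5
    library_size_min: int = 50_000
    library_size_max: int = 150_000
    # UTRs
    n_utrs: int = 100
    utr_length: int = 500

    def __post_init__(self) -> None:
        for name in ("sub_rate_5p", "sub_rate_3p", "indel_rate", "tail_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        if not 0.0 < self.dominant_fraction < 100.0:
            raise ValueError(
                f"dominant_fraction must be in (0, 100), got {self.dominant_fraction}"
            )
        if self.dispersion_control <= 0 or self.dispersion_disease <= 0:
            raise ValueError("Dirichlet concentrations must be positive")

    @property
    def effective_background_rate(self) -> float:
        if self.background_rate is not None:
            return self.background_rate
        return min(1.0, 1.5 * max(self.sub_rate_5p, self.sub_rate_3p))

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        if "mature_length_bounds" in data:
            data["mature_length_bounds"] = tuple(data["mature_length_bounds"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mature_length_bounds"] = list(d["mature_length_bounds"])
        return d


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams so the generators cannot cross-contaminate."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        old = chars[pos]
        alternatives = [nt for nt in "ACGU" if nt != old]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# phylogenetic families

@dataclass
class PhyloFamilies:
    hairpins: dict[str, list[HairpinRecord]]  # species -> hairpins
    matures: dict[str, list[MatureRecord]]  # species -> matures (both arms)
    truth: pd.DataFrame  # family, species, arm, n_substitutions, mature_length
    species: list[str]

    def family_rows(self, family: str, arm: str) -> dict[str, str]:
        """Per-species mature sequences of one family arm (equal-length, pre-aligned)."""
        suffix = f"-{family}-{arm}"
        out = {}
        for sp, mats in self.matures.items():
            for m in mats:
                if m.id == f"{sp}{suffix}":
                    out[sp] = m.sequence
        return out


def generate_phylo_families(
    cfg: SyntheticConfig, *, out_dir: str | Path | None = None
) -> PhyloFamilies:
    """Simulate miRNA families across species with arm-specific conservation.

    The reference species ``hsa`` carries the unmutated root hairpin; every
    other species' hairpin accumulates i.i.d. substitutions at
    ``sub_rate_5p`` within the 5p mature, ``sub_rate_3p`` within the 3p
    mature and the (faster) background rate elsewhere, plus loop-only
    deletions at ``indel_rate`` and up to ``terminal_jitter_max`` nt trimmed
    from each hairpin end.  Mature arms stay colinear across species, so
    family arms can be fed to the alignment stage either pre-aligned or raw.
    """
    rng = _rng_streams(cfg.seed, 3)[0]
    species = ["hsa"] + [f"sp{i}" for i in range(1, cfg.n_species)]
    lo, hi = cfg.mature_length_bounds
    bg = cfg.effective_background_rate

    total_families = cfg.n_families + cfg.n_partial_families
    hairpins: dict[str, list[HairpinRecord]] = {sp: [] for sp in species}
    matures: dict[str, list[MatureRecord]] = {sp: [] for sp in species}
    truth_rows = []
    for fam_idx in range(total_families):
        fam = f"mir-{fam_idx + 1}"
        partial = fam_idx >= cfg.n_families
        if partial:
            k = int(rng.integers(1, cfg.n_species))  # proper subset
            present = set(rng.choice(cfg.n_species, size=k, replace=False))
        else:
            present = set(range(cfg.n_species))

        len5 = int(np.clip(np.round(rng.normal(cfg.mature_length_mean, cfg.mature_length_sd)), lo, hi))
        len3 = int(np.clip(np.round(rng.normal(cfg.mature_length_mean, cfg.mature_length_sd)), lo, hi))
        L = cfg.hairpin_length
        margin = 8
        start5 = margin  # 0-based
        end3 = L - margin  # exclusive
        start3 = end3 - len3
        loop_lo, loop_hi = start5 + len5, start3  # loop region, 0-based half-open
        if loop_hi - loop_lo < 6:
            raise ValueError("hairpin_length too small for two matures plus a loop")
        root = _random_rna(rng, L)

        region = np.full(L, "bg", dtype=object)
        region[start5 : start5 + len5] = "5p"
        region[start3:end3] = "3p"
        rates = np.where(region == "5p", cfg.sub_rate_5p, np.where(region == "3p", cfg.sub_rate_3p, bg))

        for sp_idx, sp in enumerate(species):
            if sp_idx not in present:
                continue
            if sp == "hsa":
                seq = root
                n5 = n3 = 0
                s5, s3 = start5, start3
            else:
                hit = rng.random(L) < rates
                positions = np.flatnonzero(hit)
                seq = _mutate(root, positions, rng)
                n5 = int(np.sum(hit[start5 : start5 + len5]))
                n3 = int(np.sum(hit[start3:end3]))
                # loop deletions keep both arms intact; 3p coordinates shift left
                loop_del = np.flatnonzero(
                    rng.random(loop_hi - loop_lo) < cfg.indel_rate
                )
                if len(loop_del):
                    keep = [
                        i
                        for i in range(L)
                        if not (loop_lo <= i < loop_hi and (i - loop_lo) in set(loop_del))
                    ]
                    seq = "".join(seq[i] for i in keep)
                s5 = start5
                s3 = start3 - len(loop_del)
                # terminal jitter: trim hairpin ends without touching the arms
                d5 = int(rng.integers(0, cfg.terminal_jitter_max + 1))
                d3 = int(rng.integers(0, cfg.terminal_jitter_max + 1))
                d5 = min(d5, s5)
                seq = seq[d5 : len(seq) - d3] if d3 else seq[d5:]
                s5 -= d5
                s3 -= d5

            hp_id = f"{sp}-{fam}"
            hairpins[sp].append(HairpinRecord(id=hp_id, sequence=seq))
            m5 = MatureRecord(
                id=f"{sp}-{fam}-5p",
                sequence=seq[s5 : s5 + len5],
                hairpin_ids=[hp_id],
                start=s5 + 1,
                end=s5 + len5,
            )
            m3 = MatureRecord(
                id=f"{sp}-{fam}-3p",
                sequence=seq[s3 : s3 + len3],
                hairpin_ids=[hp_id],
                start=s3 + 1,
                end=s3 + len3,
            )
            matures[sp].extend([m5, m3])
            truth_rows.append(
                {"family": fam, "species": sp, "arm": "5p", "n_substitutions": n5, "mature_length": len5}
            )
            truth_rows.append(
                {"family": fam, "species": sp, "arm": "3p", "n_substitutions": n3, "mature_length": len3}
            )

    result = PhyloFamilies(
        hairpins=hairpins,
        matures=matures,
        truth=pd.DataFrame(truth_rows),
        species=species,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in species:
            write_fasta(hairpins[sp], out / f"{sp}_hairpin.fa")
            write_fasta(matures[sp], out / f"{sp}_mature.fa")
        result.truth.to_csv(out / "phylo_truth.tsv", sep="\t", index=False)
    return result


# ---------------------------------------------------------------------------
# isomiR read sets

def _offset_template(cfg: SyntheticConfig) -> tuple[list[tuple[int, int]], np.ndarray]:
    """IsomiR template proportions: canonical gets dominant_fraction percent,
    the remainder spread over (offset5, offset3) pairs with weight
    2^-(|o5|+|o3|) — end variability concentrated 1-2 nt around the dominant
    sequence."""
    keys = [
        (o5, o3)
        for o5 in range(-cfg.offset_max, cfg.offset_max + 1)
        for o3 in range(-cfg.offset_max, cfg.offset_max + 1)
    ]
    weights = np.array(
        [0.0 if k == (0, 0) else 2.0 ** -(abs(k[0]) + abs(k[1])) for k in keys]
    )
    weights = weights / weights.sum() * (1.0 - cfg.dominant_fraction / 100.0)
    probs = np.where(
        [k == (0, 0) for k in keys], cfg.dominant_fraction / 100.0, weights
    )
    return keys, probs


@dataclass
class IsomirSimulation:
    readsets: list[ReadSet]
    truth: pd.DataFrame  # sample, locus, offset5, offset3, true_proportion


def generate_isomir_readsets(
    cfg: SyntheticConfig,
    loci: Sequence[tuple[HairpinRecord, MatureRecord]],
    *,
    out_dir: str | Path | None = None,
) -> IsomirSimulation:
    """Per-sample collapsed read sets with Dirichlet-multinomial isomiR counts.

    For each sample and locus, isomiR proportions are drawn from
    Dirichlet(concentration x template) with the condition-specific
    concentration, counts are multinomial at a uniform random library size,
    and a ``tail_probability`` fraction of each isomiR's reads receives a
    non-template 3' addition (first tail base forced off-template so the
    tail is not reabsorbed by mapping).
    """
    rng = _rng_streams(cfg.seed, 3)[1]
    keys, template = _offset_template(cfg)
    anchors = []
    for hairpin, canonical in loci:
        idx = hairpin.sequence.find(canonical.sequence)
        if idx < 0:
            raise ValueError(f"canonical {canonical.id!r} not on hairpin {hairpin.id!r}")
        anchors.append((hairpin, canonical, idx, idx + len(canonical.sequence)))

    samples = [("disease", f"dis{i:03d}", cfg.dispersion_disease) for i in range(cfg.n_samples_disease)]
    samples += [("control", f"ctl{i:03d}", cfg.dispersion_control) for i in range(cfg.n_samples_control)]

    readsets: list[ReadSet] = []
    truth_rows = []
    n_loci = len(anchors)
    for condition, sample_id, concentration in samples:
        library = int(rng.integers(cfg.library_size_min, cfg.library_size_max + 1))
        per_locus = rng.multinomial(library, np.full(n_loci, 1.0 / n_loci)) if n_loci else []
        reads: dict[str, int] = {}
        for (hairpin, canonical, cs, ce), locus_n in zip(anchors, per_locus):
            props = rng.dirichlet(concentration * template)
            counts = rng.multinomial(locus_n, props)
            hp = hairpin.sequence
            for (o5, o3), prop, count in zip(keys, props, counts):
                truth_rows.append(
                    {
                        "sample": sample_id,
                        "condition": condition,
                        "locus": canonical.id,
                        "offset5": o5,
                        "offset3": o3,
                        "true_proportion": float(prop),
                    }
                )
                if count == 0:
                    continue
                lo, hi = cs + o5, ce + o3
                if lo < 0 or hi > len(hp) or hi - lo < 15:
                    continue
                body = hp[lo:hi]
                n_tailed = int(rng.binomial(count, cfg.tail_probability))
                if count - n_tailed:
                    reads[body] = reads.get(body, 0) + (count - n_tailed)
                if n_tailed:
                    lengths = np.minimum(
                        rng.geometric(0.5, size=n_tailed), cfg.max_tail_length
                    )
                    for tl in np.unique(lengths):
                        n_at = int(np.sum(lengths == tl))
                        tail = _nontemplate_tail(rng, hp, hi, int(tl))
                        seq = body + tail
                        reads[seq] = reads.get(seq, 0) + n_at
        readsets.append(
            ReadSet(
                sample_id=sample_id,
                condition=condition,
                reads=sorted(reads.items()),
            )
        )

    truth = pd.DataFrame(truth_rows)
    sim = IsomirSimulation(readsets=readsets, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for rs in readsets:
            fname = f"{rs.sample_id}.tsv"
            pd.DataFrame(rs.reads, columns=["sequence", "count"]).to_csv(
                out / fname, sep="\t", index=False, header=False
            )
            manifest.append({"sample_id": rs.sample_id, "condition": rs.condition, "path": fname})
        pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
        truth.to_csv(out / "isomir_truth.tsv", sep="\t", index=False)
    return sim


def _nontemplate_tail(
    rng: np.random.Generator, hairpin_seq: str, after: int, length: int
) -> str:
    """Random tail whose first base differs from the templated continuation."""
    bases = list(rng.choice(NUCLEOTIDES, size=length))
    if after < len(hairpin_seq):
        nxt = hairpin_seq[after]
        alternatives = [nt for nt in "ACGU" if nt != nxt]
        bases[0] = alternatives[rng.integers(3)]
    return "".join(bases)


# ---------------------------------------------------------------------------
# UTRs

@dataclass
class UtrSimulation:
    utrs: list[tuple[str, str]]  # (utr_id, sequence)
    truth: pd.DataFrame  # utr_id, seed_source, position


def generate_utrs(
    cfg: SyntheticConfig,
    seeds: Sequence[SeedSequence],
    planted_fraction: float,
    *,
    out_dir: str | Path | None = None,
) -> UtrSimulation:
    """Random UTRs with reverse-complement seed sites planted independently.

    Each UTR carries, for each seed independently with probability
    ``planted_fraction``, one planted site at a position chosen to avoid
    overlap with previously planted sites (so the truth table remains exact).
    Background (chance) matches can still occur, as in real UTRs.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    rng = _rng_streams(cfg.seed, 3)[2]
    utrs: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(cfg.n_utrs):
        uid = f"utr{i:04d}"
        seq = list(_random_rna(rng, cfg.utr_length))
        occupied: list[tuple[int, int]] = []
        for sd in seeds:
            if rng.random() >= planted_fraction:
                continue
            site = reverse_complement(sd.seed)
            for _ in range(50):
                pos = int(rng.integers(0, cfg.utr_length - len(site) + 1))
                if all(pos + len(site) <= lo or pos >= hi for lo, hi in occupied):
                    seq[pos : pos + len(site)] = list(site)
                    occupied.append((pos, pos + len(site)))
                    truth_rows.append(
                        {"utr_id": uid, "seed_source": sd.source_id, "position": pos + 1}
                    )
                    break
        utrs.append((uid, "".join(seq)))

    truth = pd.DataFrame(truth_rows, columns=["utr_id", "seed_source", "position"])
    sim = UtrSimulation(utrs=utrs, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "utrs.fa", "w") as fh:
            for uid, seq in utrs:
                fh.write(f">{uid}\n{seq}\n")
        truth.to_csv(out / "utr_truth.tsv", sep="\t", index=False)
    return sim
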