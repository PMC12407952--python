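"""Synthetic genome collections with a planted 7-rank taxonomy.

A root sequence drawn uniformly over ACGT is propagated down a rank tree;
each child is an i.i.d. per-site mutant of its parent at the branch's
substitution rate (a substituted site changes to one of the three other
bases uniformly), leaves are strains.  Substitution-only by default so
closed-form expectations stay available: two siblings at branch rate r
differ at an expected fraction d = 2r − (4/3)r² of sites, and the Mash
ANI estimate of such a pair concentrates around 100·(1 + ln(1−d)).

Everything is deterministic given the seed; equal seeds give byte-equal
FASTA output.  The default scenario (one lineage down to a single family,
3 genera, 3 species per genus, 10 strains per species, 50 kb genomes,
species-branch rate 0.08, strain rate 0.01) puts within-species ANI near
98 and between-species ANI far below the 95%-ANI species convention, so
species are unambiguous.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .kmers import RANKS
from .taxonomy import Lineage

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RankLevel:
    children: int
    rate: float  # substitution rate per site on the branch into each child

    def __post_init__(self) -> None:
        if self.children < 1:
            raise ValueError("children must be >= 1")
        if not 0 <= self.rate < 0.75:
            raise ValueError("rate must be in [0, 0.75)")


def default_ranks_spec() -> dict[str, RankLevel]:
    return {
        "kingdom": RankLevel(1, 0.0),
        "phylum": RankLevel(1, 0.0),
        "class": RankLevel(1, 0.0),
        "order": RankLevel(1, 0.0),
        "family": RankLevel(1, 0.0),
        "genus": RankLevel(3, 0.04),
        "species": RankLevel(3, 0.08),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 50_000
    ranks_spec: dict[str, RankLevel] = field(default_factory=default_ranks_spec)
    n_strains_per_species: int = 10
    strain_rate: float = 0.01
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if set(self.ranks_spec) != set(RANKS):
            raise ValueError("ranks_spec must cover all 7 ranks")
        if not 0 <= self.strain_rate < 0.75:
            raise ValueError("strain_rate must be in [0, 0.75)")
        if self.n_strains_per_species < 1:
            raise ValueError("n_strains_per_species must be >= 1")

    def to_document(self) -> dict:
        return {
            "seed": self.seed,
            "genome_length": self.genome_length,
            "ranks_spec": {r: [lv.children, lv.rate]
                           for r, lv in self.ranks_spec.items()},
            "n_strains_per_species": self.n_strains_per_species,
            "strain_rate": self.strain_rate,
            "indel_rate": self.indel_rate,
        }


def mutate(codes: np.ndarray, rate: float, rng: np.random.Generator,
           indel_rate: float = 0.0) -> np.ndarray:
    """Per-site substitution (to one of the 3 other bases) at ``rate``."""
    out = codes.copy()
    if rate > 0:
        mask = rng.random(out.size) < rate
        offsets = rng.integers(1, 4, size=int(mask.sum()))
        out[mask] = (out[mask] + offsets) % 4
    if indel_rate > 0:
        keep = rng.random(out.size) >= indel_rate  # deletions
        out = out[keep]
        n_ins = rng.binomial(out.size, indel_rate)
        pos = np.sort(rng.integers(0, out.size + 1, size=n_ins))
        out = np.insert(out, pos, rng.integers(0, 4, size=n_ins))
    return out


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass
class TruthTable:
    rows: pd.DataFrame  # genome_id, lineage, branch_rates

    def lineages(self) -> dict[str, Lineage]:
        from .taxonomy import parse_lineage
        return {r.genome_id: parse_lineage(r.lineage) for r in self.rows.itertuples()}

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def simulate_collection(
    config: SimulationConfig,
    out_dir: Optional[str | Path] = None,
    gzip_fasta: bool = False,
) -> tuple[dict[str, str], TruthTable]:
    """Generate the genome collection and its planted taxonomy.

    Returns (genome_id -> sequence, truth table); when ``out_dir`` is
    given, also writes one FASTA per genome, the truth taxonomy TSV and a
    config echo JSON.
    """
    rng = np.random.default_rng(config.seed)
    root = rng.integers(0, 4, size=config.genome_length).astype(np.uint8)
    prefixes = {"kingdom": "K", "phylum": "P", "class": "C", "order": "O",
                "family": "F", "genus": "G", "species": "S"}
    # breadth-first expansion rank by rank
    nodes: list[tuple[list[str], np.ndarray]] = [([], root)]
    counters = {r: 0 for r in RANKS}
    for rank in RANKS:
        level = config.ranks_spec[rank]
        expanded = []
        for labels, codes in nodes:
            for _ in range(level.children):
                counters[rank] += 1
                child_label = f"{prefixes[rank]}{counters[rank]}"
                child = mutate(codes, level.rate, rng, config.indel_rate)
                expanded.append((labels + [child_label], child))
        nodes = expanded
    genomes: dict[str, str] = {}
    rows = []
    for labels, codes in nodes:
        species = labels[-1]
        lineage = Lineage.of(*labels)
        for s in range(1, config.n_strains_per_species + 1):
            gid = f"{species}_{s:02d}"
            strain = mutate(codes, config.strain_rate, rng, config.indel_rate)
            genomes[gid] = _codes_to_seq(strain)
            rows.append({
                "genome_id": gid,
                "lineage": lineage.serialize(),
                "branch_rates": ";".join(
                    f"{config.ranks_spec[r].rate:g}" for r in RANKS
                ) + f";{config.strain_rate:g}",
            })
    truth = TruthTable(pd.DataFrame(rows, columns=["genome_id", "lineage",
                                                   "branch_rates"]))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for gid in sorted(genomes):
            name = f"{gid}.fasta" + (".gz" if gzip_fasta else "")
            payload = f">{gid}\n{genomes[gid]}\n"
            if gzip_fasta:
                with gzip.open(out_dir / name, "wt") as fh:
                    fh.write(payload)
            else:
                (out_dir / name).write_text(payload)
        truth.to_tsv(out_dir / "taxonomy.tsv")
        (out_dir / "config.json").write_text(
            json.dumps(config.to_document(), indent=2, sort_keys=True) + "\n")
    return genomes, truth


def plant_mislabels(
    truth: TruthTable, fraction: float, seed: int
) -> tuple[pd.DataFrame, list[str]]:
    """Corrupt a seeded random subset of genomes with a wrong species lineage.

    Each corrupted genome takes the full lineage of a different, randomly
    chosen species.  Returns (corrupted taxonomy table, answer key of
    corrupted genome ids).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    df = truth.rows.copy()
    species_lineages = sorted(set(df.lineage))
    n_corrupt = int(round(fraction * len(df)))
    answer = sorted(rng.choice(df.genome_id.to_numpy(), size=n_corrupt,
                               replace=False).tolist())
    lineage_by_id = dict(zip(df.genome_id, df.lineage))
    for gid in answer:
        others = [lin for lin in species_lineages if lin != lineage_by_id[gid]]
        lineage_by_id[gid] = others[rng.integers(0, len(others))]
    df["lineage"] = df.genome_id.map(lineage_by_id)
    return df[["genome_id", "lineage"]], answer
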