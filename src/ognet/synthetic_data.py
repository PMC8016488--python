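"""Synthetic orthologous-group databases with known ground truth.

Real orthology databases are dominated by two features that make classifier
evaluation hard: group-specific sequence motifs (what convolutional filters
learn to detect) and heavily imbalanced group populations, down to singletons.
This module emulates exactly those two features and nothing else: sequences are
i.i.d. uniform background over the 20 standard residues, with each family's
consensus motifs implanted at fixed relative positions and mutated per site.

The substitution model redraws a mutated site uniformly over all 20 residues,
so it may silently retain the original: the expected per-site retention under
mutation probability m is (1 - m) + m/20, which makes a closed-form oracle for
the generator's own tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .alphabet_io import STANDARD_RESIDUES, ProteinRecord, write_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifSpec:
    """A conserved ungapped motif implanted into every member of a family.

    ``relative_position`` is the fraction of the (length - motif) span at which
    the motif starts; ``per_site_mutation_prob`` is the chance each site is
    redrawn uniformly over the 20 standard residues.
    """

    consensus: str
    relative_position: float
    per_site_mutation_prob: float

    def __post_init__(self):
        if not set(self.consensus) <= set(STANDARD_RESIDUES):
            raise ValueError("motif consensus must use the 20 standard residues")
        if not 0.0 <= self.relative_position <= 1.0:
            raise ValueError("relative_position must lie in [0, 1]")
        if not 0.0 <= self.per_site_mutation_prob <= 1.0:
            raise ValueError("per_site_mutation_prob must lie in [0, 1]")


@dataclass(frozen=True)
class FamilySpec:
    """One orthologous group: its motifs, length law and population."""

    group_id: str
    motifs: tuple[MotifSpec, ...]
    length_law: tuple[int, int]  # inclusive uniform integer bounds
    population: int

    def __post_init__(self):
        lo, hi = self.length_law
        longest = max((len(m.consensus) for m in self.motifs), default=0)
        if lo < longest:
            raise ValueError(
                f"minimum length {lo} shorter than longest motif ({longest}) in {self.group_id}"
            )
        if lo > hi:
            raise ValueError("length_law must satisfy min <= max")
        if self.population < 1:
            raise ValueError("population must be >= 1")


@dataclass
class DatasetManifest:
    seed: int
    families: list[FamilySpec]
    totals: dict[str, int]


def sample_family_specs(
    n_groups: int,
    motifs_per_group: int = 3,
    imbalance_exponent: float = 0.0,
    base_population: int = 100,
    length_range: tuple[int, int] = (80, 300),
    seed: int = 0,
    mutation_prob: float = 0.05,
    motif_length_range: tuple[int, int] = (6, 12),
    group_prefix: str = "OG",
) -> list[FamilySpec]:
    """Draw family specifications with a power-law population profile.

    The family ranked r (1-based) has population round(base_population * r^-e),
    floored at 1, so exponent 0 gives balanced groups and larger exponents give
    the long singleton tail typical of orthology databases. Motif consensi are
    drawn independently per family; identical seeds give identical specs.
    """
    if n_groups < 1:
        raise ValueError("need at least one group")
    if imbalance_exponent < 0:
        raise ValueError("imbalance_exponent must be >= 0")
    if length_range[0] < motif_length_range[1]:
        raise ValueError(
            f"minimum sequence length {length_range[0]} cannot accommodate "
            f"motifs up to length {motif_length_range[1]}"
        )
    rng = np.random.default_rng(seed)
    residues = np.array(list(STANDARD_RESIDUES))
    specs = []
    for r in range(1, n_groups + 1):
        population = max(1, round(base_population * r ** (-imbalance_exponent)))
        motifs = []
        for _ in range(motifs_per_group):
            m_len = int(rng.integers(motif_length_range[0], motif_length_range[1] + 1))
            consensus = "".join(rng.choice(residues, size=m_len))
            motifs.append(
                MotifSpec(
                    consensus=consensus,
                    relative_position=float(rng.uniform()),
                    per_site_mutation_prob=mutation_prob,
                )
            )
        specs.append(
            FamilySpec(
                group_id=f"{group_prefix}{r:04d}",
                motifs=tuple(motifs),
                length_law=length_range,
                population=population,
            )
        )
    return specs


def sample_sequence(
    family: FamilySpec, rng: np.random.Generator, record_id: str | None = None
) -> tuple[ProteinRecord, str]:
    """Draw one member of a family: uniform background plus implanted motifs.

    Motifs are implanted in listed order at floor(relative_position * (L - |m|)),
    so a later motif overwrites an earlier one where they overlap. Each motif
    site then mutates independently: with probability per_site_mutation_prob it
    is redrawn uniformly over the 20 standard residues.
    """
    residues = np.array(list(STANDARD_RESIDUES))
    lo, hi = family.length_law
    length = int(rng.integers(lo, hi + 1))
    seq = rng.choice(residues, size=length)
    for motif in family.motifs:
        m = np.array(list(motif.consensus))
        start = int(np.floor(motif.relative_position * (length - len(m))))
        mutate = rng.random(len(m)) < motif.per_site_mutation_prob
        substituted = rng.choice(residues, size=len(m))
        seq[start : start + len(m)] = np.where(mutate, substituted, m)
    rid = record_id or f"{family.group_id}_seq"
    record = ProteinRecord(
        id=rid, description=f"{rid} synthetic member of {family.group_id}", sequence="".join(seq)
    )
    return record, family.group_id


def generate_dataset(
    specs: list[FamilySpec],
    out_fasta: str | Path,
    out_labels: str | Path,
    seed: int = 0,
    out_manifest: str | Path | None = None,
) -> DatasetManifest:
    """Write a FASTA + label TSV for the given families; deterministic in seed."""
    rng = np.random.default_rng(seed)
    totals: dict[str, int] = {}
    labels: list[tuple[str, str]] = []
    out_fasta = Path(out_fasta)
    with out_fasta.open("w") as fh:
        for family in specs:
            for k in range(family.population):
                rid = f"{family.group_id}_{k:05d}"
                record, group = sample_sequence(family, rng, record_id=rid)
                fh.write(f">{record.id} {family.group_id}\n{record.sequence}\n")
                labels.append((record.id, group))
            totals[family.group_id] = family.population
    write_labels(labels, out_labels)
    manifest = DatasetManifest(seed=seed, families=list(specs), totals=totals)
    if out_manifest is not None:
        with Path(out_manifest).open("w") as fh:
            json.dump(
                {
                    "seed": seed,
                    "totals": totals,
                    "families": [asdict(f) for f in specs],
                },
                fh,
                indent=1,
            )
    logger.info(
        "wrote %d sequences across %d families to %s", sum(totals.values()), len(specs), out_fasta
    )
    return manifest


def generate_records(
    specs: list[FamilySpec], seed: int = 0
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """In-memory variant of :func:`generate_dataset` (same draws, no files)."""
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    for family in specs:
        for k in range(family.population):
            rid = f"{family.group_id}_{k:05d}"
            record, group = sample_sequence(family, rng, record_id=rid)
            records.append(record)
            labels[rid] = group
    return records, labels
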