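"""Synthetic panels, genotypes, expression weights and paired-end reads.

The generator emulates the structure of a capture RNA-Seq experiment over
the classical HLA loci: a reference panel of allele transcripts whose
polymorphic-exon windows have the canonical per-locus lengths; diploid
genotypes in which each haplotype carries at most one of the DRB3/DRB4/DRB5
paralogs; allele-level expression weights (locus mean x log-normal allelic
deviation x log-normal capture-efficiency bias); and 2x150 bp paired reads
with uniform per-base substitution errors.  Every output is deterministic
under a fixed seed, and the sampled weights are written to a truth table so
downstream estimates can be checked against them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    AlleleName,
    AlleleReference,
    ExonWindow,
    Locus,
    ReferenceSet,
    WINDOW_SPECS,
)

__all__ = [
    "SimConfig",
    "DEFAULT_LOCUS_MEANS",
    "synthesize_panel",
    "simulate_genotypes",
    "simulate_expression",
    "emit_reads",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: Default locus-level mean expression weights.  These follow the ordering
#: observed in healthy PBMC cohorts (B > C > A among class I; DRA and DRB1
#: highest among class II; DQA1/DQB1 lowest; DRB4/DRB5 above DRB3), on an
#: arbitrary relative scale.
DEFAULT_LOCUS_MEANS: Mapping[Locus, float] = {
    Locus.A: 86_788.0,
    Locus.B: 165_092.0,
    Locus.C: 98_672.0,
    Locus.DPA1: 12_585.0,
    Locus.DPB1: 20_354.0,
    Locus.DQA1: 7_744.0,
    Locus.DQB1: 8_096.0,
    Locus.DRA: 36_511.0,
    Locus.DRB1: 35_606.0,
    Locus.DRB3: 9_972.0,
    Locus.DRB4: 15_445.0,
    Locus.DRB5: 13_634.0,
}

#: Per-haplotype probability of carrying each secondary DR paralog (the
#: remainder is "no secondary DRB gene on this haplotype").
DEFAULT_DRB_HAPLOTYPE_MODEL: Mapping[Locus | None, float] = {
    Locus.DRB3: 0.35,
    Locus.DRB4: 0.30,
    Locus.DRB5: 0.20,
    None: 0.15,
}


@dataclass
class SimConfig:
    """Parameters of the read simulator.

    ``depth`` is the target number of window-overlapping ("in-phase") read
    pairs per sample.  ``allelic_sigma_class1``/``allelic_sigma_class2`` are
    log-normal sigmas for the per-allele multiplicative expression
    deviation; the class II default is larger, giving class II loci the
    wider allelic spread seen in real cohorts.  ``capture_bias_sigma``
    models per-allele probe-capture efficiency differences (constant across
    fragments of an allele).
    """

    n_samples: int = 20
    locus_mean_expression: Mapping[Locus, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCUS_MEANS)
    )
    allelic_sigma_class1: float = 0.15
    allelic_sigma_class2: float = 0.5
    depth: int = 2000
    read_length: int = 150
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    error_rate: float = 0.001
    capture_bias_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed mean fragment length")
        for sigma in (
            self.allelic_sigma_class1,
            self.allelic_sigma_class2,
            self.capture_bias_sigma,
        ):
            if sigma < 0:
                raise ValueError("log-normal sigmas must be non-negative")

    def allelic_sigma(self, locus: Locus) -> float:
        return (
            self.allelic_sigma_class1
            if locus.hla_class == "I"
            else self.allelic_sigma_class2
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _window_exon_lengths(window: ExonWindow) -> list[int]:
    # class I windows span two exons; split the canonical length evenly
    n = len(window.exon_ids)
    base = window.expected_length_bp // n
    lengths = [base] * n
    lengths[-1] += window.expected_length_bp - base * n
    return lengths


def synthesize_panel(
    loci: Sequence[Locus],
    alleles_per_locus: int,
    divergence: int,
    seed: int,
    flank: int = 100,
) -> ReferenceSet:
    """Generate a toy allele panel with canonical window lengths.

    Each locus gets a random base transcript (``flank`` bp on each side of
    the window exons); alleles are derived from it by ``divergence`` random
    substitutions inside the window.  With ``divergence >= 1`` the window
    sequences of a locus are guaranteed pairwise distinct; ``divergence=0``
    yields indistinguishable alleles (useful for phasing-exclusion tests)
    and triggers a warning when more than one allele is requested.
    """
    if alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if divergence == 0 and alleles_per_locus > 1:
        warnings.warn(
            "divergence=0 with multiple alleles per locus: within-locus "
            "alleles are indistinguishable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    panel = ReferenceSet()
    bases = "ACGT"
    for locus in loci:
        window = WINDOW_SPECS[locus]
        exon_lengths = _window_exon_lengths(window)
        total_window = sum(exon_lengths)
        base_seq = _random_seq(rng, flank + total_window + flank)
        win_start = flank
        # exon annotation shared by all alleles of the locus
        exon_table = []
        pos = win_start
        for exon_id, length in zip(window.exon_ids, exon_lengths):
            exon_table.append((exon_id, pos, pos + length))
            pos += length
        for attempt in range(200):
            windows_seen: set[str] = set()
            alleles: list[AlleleReference] = []
            ok = True
            for i in range(alleles_per_locus):
                seq = list(base_seq)
                if divergence > 0:
                    positions = rng.choice(total_window, size=divergence, replace=False)
                    for p in positions:
                        old = seq[win_start + p]
                        seq[win_start + p] = bases[
                            (bases.index(old) + rng.integers(1, 4)) % 4
                        ]
                window_seq = "".join(seq[win_start : win_start + total_window])
                if divergence > 0 and window_seq in windows_seen:
                    ok = False
                    break
                windows_seen.add(window_seq)
                name = AlleleName(locus, i + 1, 1, 1)
                alleles.append(
                    AlleleReference(name, "".join(seq), tuple(exon_table))
                )
            if ok:
                for ref in alleles:
                    panel.add(ref)
                break
        else:  # pragma: no cover - probability of 200 failures is negligible
            raise RuntimeError(f"could not generate distinct alleles for {locus}")
    return panel


def simulate_genotypes(
    panel: ReferenceSet,
    n_samples: int,
    drb_haplotype_model: Mapping[Locus | None, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw diploid genotypes over the panel's loci.

    Returns a long table with columns ``sample_id, locus, haplotype_index,
    allele``.  For ordinary loci each haplotype draws an allele uniformly;
    for the DRB3/DRB4/DRB5 group each haplotype carries at most one paralog
    (or none), drawn from ``drb_haplotype_model``.
    """
    rng = np.random.default_rng(seed)
    loci = panel.loci
    drb_loci = [l for l in loci if l.is_drb_paralog]
    regular = [l for l in loci if not l.is_drb_paralog]
    if drb_haplotype_model is None:
        model = {k: v for k, v in DEFAULT_DRB_HAPLOTYPE_MODEL.items()
                 if k is None or k in drb_loci}
    else:
        model = dict(drb_haplotype_model)
    rows = []
    for s in range(n_samples):
        sample_id = f"S{s:03d}"
        for locus in regular:
            names = sorted(r.name.render() for r in panel.by_locus(locus))
            if len(names) < 2:
                raise ValueError(f"panel needs >= 2 alleles at {locus}")
            for hap in (1, 2):
                rows.append(
                    (sample_id, locus.value, hap, names[rng.integers(len(names))])
                )
        if drb_loci:
            choices = list(model)
            probs = np.array([model[c] for c in choices], dtype=float)
            probs = probs / probs.sum()
            for hap in (1, 2):
                pick = choices[rng.choice(len(choices), p=probs)]
                if pick is None:
                    continue
                names = sorted(r.name.render() for r in panel.by_locus(pick))
                rows.append(
                    (sample_id, pick.value, hap, names[rng.integers(len(names))])
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "locus", "haplotype_index", "allele"]
    )


def simulate_expression(genotypes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Attach expression and capture weights to each genotype haplotype.

    Returns the truth table with one row per (sample, haplotype, allele):
    ``true_relative_expression`` is the biological weight (locus mean x
    allelic log-normal deviation), ``capture_bias`` the per-allele capture
    efficiency, and ``sampling_weight`` their product — the weight actually
    used to draw read pairs.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for rec in genotypes.itertuples(index=False):
        locus = Locus(rec.locus)
        mean = config.locus_mean_expression.get(locus)
        if mean is None or mean <= 0:
            raise ValueError(f"no positive mean expression configured for {locus}")
        expr = mean * rng.lognormal(0.0, config.allelic_sigma(locus))
        bias = rng.lognormal(0.0, config.capture_bias_sigma)
        rows.append(
            (
                rec.sample_id,
                rec.locus,
                rec.haplotype_index,
                rec.allele,
                expr,
                bias,
                expr * bias,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "locus",
            "haplotype_index",
            "allele",
            "true_relative_expression",
            "capture_bias",
            "sampling_weight",
        ],
    )


def _window_span(ref: AlleleReference, window: ExonWindow) -> tuple[int, int]:
    intervals = [ref.exon_interval(e) for e in window.exon_ids]
    return min(s for s, _ in intervals), max(e for _, e in intervals)


def emit_reads(
    truth: pd.DataFrame,
    panel: ReferenceSet,
    config: SimConfig,
    out_dir: str | Path,
) -> dict[str, tuple[Path, Path]]:
    """Write per-sample paired FASTQ plus the truth TSV.

    Fragments are drawn from each allele's window-containing transcript,
    constrained to overlap the mapping window by at least one base, with
    lengths ~ Normal(fragment_mean, fragment_sd) clipped to
    [read_length, transcript length].  Mate 1 is the fragment 5' end, mate 2
    the reverse complement 5' end; both are ``read_length`` bases (or the
    whole fragment if shorter).  Substitution errors are applied per base at
    ``error_rate``.  Read names encode sample, allele and pair index.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2)
    bases = "ACGT"
    fastqs: dict[str, tuple[Path, Path]] = {}
    truncated_warned = False

    def maybe_errors(seq: str) -> str:
        if config.error_rate == 0:
            return seq
        n_err = rng.binomial(len(seq), config.error_rate)
        if n_err == 0:
            return seq
        arr = list(seq)
        for p in rng.choice(len(seq), size=n_err, replace=False):
            arr[p] = bases[(bases.index(arr[p]) + rng.integers(1, 4)) % 4]
        return "".join(arr)

    truth = truth.sort_values(
        ["sample_id", "locus", "haplotype_index", "allele"], kind="stable"
    )
    for sample_id, sub in truth.groupby("sample_id", sort=True):
        r1_path = out_dir / f"{sample_id}_R1.fastq"
        r2_path = out_dir / f"{sample_id}_R2.fastq"
        weights = sub["sampling_weight"].to_numpy(dtype=float)
        counts = rng.multinomial(config.depth, weights / weights.sum())
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            pair_idx = 0
            for (row, n_pairs) in zip(sub.itertuples(index=False), counts):
                ref = panel[row.allele]
                window = WINDOW_SPECS[Locus(row.locus)]
                win_start, win_end = _window_span(ref, window)
                transcript = ref.sequence
                tlen = len(transcript)
                for _ in range(int(n_pairs)):
                    frag_len = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
                    if frag_len > tlen and not truncated_warned:
                        warnings.warn(
                            "fragment longer than transcript; truncating",
                            stacklevel=2,
                        )
                        truncated_warned = True
                    frag_len = min(max(frag_len, config.read_length), tlen)
                    lo = max(0, win_start - frag_len + 1)
                    hi = min(win_end - 1, tlen - frag_len)
                    start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                    frag = transcript[start : start + frag_len]
                    r1 = maybe_errors(frag[: config.read_length])
                    r2 = maybe_errors(reverse_complement(frag)[: config.read_length])
                    name = f"sim|{sample_id}|{row.allele}|{pair_idx}"
                    f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                    f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
                    pair_idx += 1
        fastqs[str(sample_id)] = (r1_path, r2_path)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return fastqs
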