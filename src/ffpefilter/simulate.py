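"""Synthetic matched FF/FFPE call-set generator with ground truth.

The generator emulates, at the call-annotation level, the documented
statistics of FFPE damage: artifacts carry low mutation allele
frequencies (Beta with median ~0.10 vs ~0.25 for true variants), strong
read-orientation bias (an artifact-supporting read is F1R2 with
probability 0.9 vs 0.5 for true variants), a substitution spectrum
dominated by C>T/G>A deamination, positions closer to read ends, and
shorter fragments (FFPE median 147 bp vs FF 221 bp).  True variants
appear in both call sets with independently re-sampled read support;
artifacts appear in the FFPE set only.  No read-level data is simulated
-- the output is exactly the MuTect2-dialect annotations the classifier
consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import SUBSTITUTION_TYPES
from .variants import Label, VariantCall, VariantKey
from .vcf_io import write_mutect_vcf

_BASES = ("A", "C", "G", "T")


def _default_artifact_weights() -> Dict[str, float]:
    w = {s: 0.03 for s in SUBSTITUTION_TYPES}
    w["C>T"] = 0.35
    w["G>A"] = 0.35
    return w


def _default_true_weights() -> Dict[str, float]:
    return {s: 1.0 / 12.0 for s in SUBSTITUTION_TYPES}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; defaults encode the documented artifact biology."""

    n_true_variants: int = 2000
    n_artifacts: int = 2000
    true_maf_beta: Tuple[float, float] = (2.5, 7.0)      # median ~0.25
    artifact_maf_beta: Tuple[float, float] = (1.8, 14.0)  # median ~0.10
    artifact_orientation_bias: float = 0.9
    true_orientation_bias: float = 0.5
    artifact_substitution_weights: Dict[str, float] = field(default_factory=_default_artifact_weights)
    true_substitution_weights: Dict[str, float] = field(default_factory=_default_true_weights)
    depth_mean: float = 80.0
    depth_dispersion: float = 10.0
    ff_fragment_mean: float = 221.0
    ffpe_fragment_mean: float = 147.0
    fragment_sd: float = 25.0
    true_mpos_mean: float = 25.0
    artifact_mpos_mean: float = 12.0
    mpos_sd: float = 7.0
    indel_fraction_true: float = 0.08
    indel_fraction_artifact: float = 0.0
    n_chroms: int = 22
    chrom_length: int = 50_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_variants < 0 or self.n_artifacts < 0:
            raise ValueError("call counts must be >= 0")
        for name in ("artifact_orientation_bias", "true_orientation_bias",
                     "indel_fraction_true", "indel_fraction_artifact"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("artifact_substitution_weights", "true_substitution_weights"):
            w = getattr(self, name)
            if set(w) != set(SUBSTITUTION_TYPES) or any(v < 0 for v in w.values()):
                raise ValueError(f"{name} must weight exactly the 12 SNV types, nonnegatively")
        n_slots = self.n_chroms * self.chrom_length
        if self.n_true_variants + self.n_artifacts > n_slots:
            raise ValueError("more calls requested than genome positions available")


@dataclass
class SyntheticTruth:
    """Per-key truth labels plus the realised generative parameters."""

    labels: Dict[VariantKey, Label]
    params: Dict[VariantKey, Dict[str, float]]

    @property
    def true_keys(self) -> set:
        return {k for k, l in self.labels.items() if l is Label.TRUE_VARIANT}


def _draw_positions(rng: np.random.Generator, n: int, cfg: SyntheticConfig):
    seen = set()
    out = []
    while len(out) < n:
        chrom = int(rng.integers(1, cfg.n_chroms + 1))
        pos = int(rng.integers(1, cfg.chrom_length + 1))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        out.append((f"chr{chrom}", pos))
    return out


def _draw_alleles(rng: np.random.Generator, weights: Dict[str, float], indel_frac: float):
    if indel_frac > 0 and rng.random() < indel_frac:
        base = _BASES[rng.integers(0, 4)]
        extra = _BASES[rng.integers(0, 4)]
        if rng.random() < 0.5:
            return base, base + extra, "INS"
        return base + extra, base, "DEL"
    types = list(SUBSTITUTION_TYPES)
    p = np.array([weights[t] for t in types], dtype=float)
    p /= p.sum()
    sub = types[rng.choice(len(types), p=p)]
    return sub[0], sub[2], sub


def _conditioned_binomial(rng: np.random.Generator, n: int, p: float) -> int:
    """Binomial(n, p) conditioned >= 1; a called variant must have alt reads."""
    for _ in range(1000):
        k = int(rng.binomial(n, p))
        if k >= 1:
            return k
    return 1


def _draw_call(
    rng: np.random.Generator,
    key: VariantKey,
    maf: float,
    bias: float,
    fragment_mean: float,
    mpos_mean: float,
    cfg: SyntheticConfig,
) -> VariantCall:
    nb_p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    depth = max(10, int(rng.negative_binomial(cfg.depth_dispersion, nb_p)))
    ad_alt = _conditioned_binomial(rng, depth, maf)
    ad_alt = min(ad_alt, depth - 1) if depth > 1 else ad_alt
    ad_ref = depth - ad_alt
    f1r2_alt = int(rng.binomial(ad_alt, bias))
    f2r1_alt = ad_alt - f1r2_alt
    f1r2_ref = int(rng.binomial(ad_ref, 0.5))
    f2r1_ref = ad_ref - f1r2_ref
    norm = lambda mu, sd, lo, hi: float(np.clip(rng.normal(mu, sd), lo, hi))
    return VariantCall(
        key=key,
        depth=depth,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        f1r2_ref=f1r2_ref,
        f1r2_alt=f1r2_alt,
        f2r1_ref=f2r1_ref,
        f2r1_alt=f2r1_alt,
        mbq_ref=norm(31.0, 3.0, 10.0, 40.0),
        mbq_alt=norm(31.0, 3.0, 10.0, 40.0),
        mmq_ref=norm(59.0, 1.5, 20.0, 60.0),
        mmq_alt=norm(59.0, 1.5, 20.0, 60.0),
        mfrl_ref=norm(fragment_mean, cfg.fragment_sd, 50.0, 600.0),
        mfrl_alt=norm(fragment_mean, cfg.fragment_sd, 50.0, 600.0),
        mpos=norm(mpos_mean, cfg.mpos_sd, 1.0, 75.0),
        tlod=max(3.0, 1.2 * ad_alt + float(rng.normal(0.0, 2.0))),
        ecnt=int(rng.choice([1, 2, 3], p=[0.85, 0.12, 0.03])),
        popaf=norm(6.0, 0.5, 1.0, 8.0),
        germq=norm(90.0, 5.0, 30.0, 93.0),
        seqq=norm(85.0, 8.0, 30.0, 93.0),
        strandq=norm(35.0, 8.0, 10.0, 93.0),
        roq=norm(40.0, 10.0, 10.0, 93.0),
        filter_status=frozenset({"PASS"}),
    )


def generate_paired_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> Tuple[List[VariantCall], List[VariantCall], SyntheticTruth]:
    """Draw matched FF/FFPE call sets and their ground truth.

    Deterministic given ``config.seed``.  The FF call set contains exactly
    the true-variant keys, re-drawn with the same per-variant MAF but
    independent sampling noise and FF fragment lengths.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_true_variants + config.n_artifacts
    positions = _draw_positions(rng, n_total, config)

    labels: Dict[VariantKey, Label] = {}
    params: Dict[VariantKey, Dict[str, float]] = {}
    ffpe_calls: List[VariantCall] = []
    ff_calls: List[VariantCall] = []

    specs = []
    for i, (chrom, pos) in enumerate(positions):
        is_true = i < config.n_true_variants
        if is_true:
            ref, alt, sub = _draw_alleles(rng, config.true_substitution_weights,
                                          config.indel_fraction_true)
            maf = float(rng.beta(*config.true_maf_beta))
            bias = config.true_orientation_bias
        else:
            ref, alt, sub = _draw_alleles(rng, config.artifact_substitution_weights,
                                          config.indel_fraction_artifact)
            maf = float(rng.beta(*config.artifact_maf_beta))
            bias = config.artifact_orientation_bias
        maf = min(max(maf, 0.005), 0.999)
        key = VariantKey(chrom, pos, ref, alt)
        specs.append((key, is_true, maf, bias, sub))

    # sort by genome coordinate so emitted VCFs are position-sorted
    specs.sort(key=lambda s: (int(s[0].chrom[3:]), s[0].pos, s[0].alt))
    for key, is_true, maf, bias, sub in specs:
        labels[key] = Label.TRUE_VARIANT if is_true else Label.FFPE_ARTIFACT
        params[key] = {"drawn_maf": maf, "drawn_bias": bias, "substitution": sub}
        ffpe_calls.append(
            _draw_call(rng, key, maf, bias, config.ffpe_fragment_mean,
                       config.true_mpos_mean if is_true else config.artifact_mpos_mean, config)
        )
        if is_true:
            ff_calls.append(
                _draw_call(rng, key, maf, config.true_orientation_bias,
                           config.ff_fragment_mean, config.true_mpos_mean, config)
            )
    return ff_calls, ffpe_calls, SyntheticTruth(labels, params)


def write_pair(
    ff_calls: Sequence[VariantCall],
    ffpe_calls: Sequence[VariantCall],
    truth: SyntheticTruth,
    directory: str,
    sample_id: str = "synthetic",
    config: Optional[SyntheticConfig] = None,
) -> Dict[str, str]:
    """Emit ff.vcf, ffpe.vcf and truth.tsv into ``directory``."""
    os.makedirs(directory, exist_ok=True)
    cfg = config or SyntheticConfig()
    contigs = {f"chr{i}": cfg.chrom_length + 2000 for i in range(1, cfg.n_chroms + 1)}
    paths = {
        "ff": os.path.join(directory, f"{sample_id}.ff.vcf"),
        "ffpe": os.path.join(directory, f"{sample_id}.ffpe.vcf"),
        "truth": os.path.join(directory, f"{sample_id}.truth.tsv"),
    }
    write_mutect_vcf(ff_calls, paths["ff"], sample=sample_id, contigs=contigs)
    write_mutect_vcf(ffpe_calls, paths["ffpe"], sample=sample_id, contigs=contigs)
    rows = []
    for c in ffpe_calls:
        k = c.key
        p = truth.params.get(k, {})
        rows.append({
            "sample_id": sample_id, "chrom": k.chrom, "pos": k.pos, "ref": k.ref,
            "alt": k.alt, "label": truth.labels[k].value,
            "drawn_maf": round(p.get("drawn_maf", float("nan")), 6),
            "drawn_bias": p.get("drawn_bias", float("nan")),
        })
    tmp = paths["truth"] + ".tmp"
    pd.DataFrame(rows).to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, paths["truth"])
    return paths
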