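"""Ground-truth labels from matched FF/FFPE call sets and the 7:3 split.

An FFPE call whose (chrom, pos, ref, alt) key is also present in the
matched fresh-frozen PASS call set is a true variant; an FFPE-only call is
an FFPE-induced artifact.  Matching is at full allele granularity and
chromosome names are compared verbatim -- both call sets are expected to
come from one pipeline.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .variants import Label, LabeledVariant, VariantCall


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation partition parameters: per-file random split."""

    train_fraction: float = 0.7
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction <= 1.0):
            raise ValueError(f"train_fraction must be in (0, 1], got {self.train_fraction}")


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    cancer_type: Optional[str]
    ff_path: str
    ffpe_path: str


def _check_unique(calls: Sequence[VariantCall], which: str) -> None:
    seen = set()
    for c in calls:
        if c.key in seen:
            raise ValueError(f"duplicate VariantKey {c.key} in {which} call set: ambiguous matching")
        seen.add(c.key)


def label_ffpe_calls(
    ffpe_calls: Sequence[VariantCall],
    ff_calls: Sequence[VariantCall],
    sample_id: str = "",
    cancer_type: Optional[str] = None,
) -> List[LabeledVariant]:
    """Label every FFPE call by presence of its key in the FF call set.

    FF-only calls do not appear in the output; the two label groups
    partition the FFPE calls exactly.
    """
    _check_unique(ffpe_calls, "FFPE")
    _check_unique(ff_calls, "FF")
    ff_keys = {c.key for c in ff_calls}
    return [
        LabeledVariant(
            call=c,
            label=Label.TRUE_VARIANT if c.key in ff_keys else Label.FFPE_ARTIFACT,
            sample_id=sample_id,
            cancer_type=cancer_type,
        )
        for c in ffpe_calls
    ]


def split_train_validation(
    labeled: Sequence[LabeledVariant],
    spec: SplitSpec = SplitSpec(),
) -> Tuple[List[LabeledVariant], List[LabeledVariant]]:
    """Random per-sample split at the given ratio (default 7:3).

    Each sample's calls are split independently; the train side gets
    round-half-up(train_fraction * n) calls.  Deterministic given the seed:
    samples are visited in sorted order and each gets its own RNG stream.
    """
    if not labeled:
        raise ValueError("cannot split an empty call set")
    by_sample: Dict[str, List[LabeledVariant]] = {}
    for lv in labeled:
        by_sample.setdefault(lv.sample_id, []).append(lv)
    train: List[LabeledVariant] = []
    valid: List[LabeledVariant] = []
    for idx, sid in enumerate(sorted(by_sample)):
        group = by_sample[sid]
        n = len(group)
        n_train = int(math.floor(spec.train_fraction * n + 0.5))  # round half up
        rng = np.random.default_rng([spec.seed, idx])
        order = rng.permutation(n)
        train.extend(group[i] for i in order[:n_train])
        valid.extend(group[i] for i in order[n_train:])
    return train, valid


def exclude_training_overlap(
    validation: Sequence[LabeledVariant],
    train: Sequence[LabeledVariant],
) -> List[LabeledVariant]:
    """Drop validation calls whose key occurred anywhere in training.

    The overlap check spans samples, so a variant contributed by one
    technical replicate during training cannot be evaluated via another.
    """
    train_keys = {lv.key for lv in train}
    return [lv for lv in validation if lv.key not in train_keys]


def read_manifest(path: str) -> List[ManifestEntry]:
    """Read the tab-separated FF/FFPE pair manifest.

    Columns: sample_id, cancer_type, ff_path, ffpe_path.  A header row
    starting with 'sample_id' is skipped.
    """
    entries: List[ManifestEntry] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "sample_id":
                continue
            if len(row) != 4:
                raise ValueError(f"manifest row needs 4 tab-separated fields, got {row!r}")
            sid, cancer, ff, ffpe = row
            entries.append(ManifestEntry(sid, cancer or None, ff, ffpe))
    return entries
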