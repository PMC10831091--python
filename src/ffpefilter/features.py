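"""The 41-entry predictor vector computed from MuTect2 call annotations.

Layout (version ``v1``):

* 22 raw caller outputs: DP, AD_ref, AD_alt, AF, F1R2_ref, F1R2_alt,
  F2R1_ref, F2R1_alt, MBQ_ref, MBQ_alt, MFRL_ref, MFRL_alt, MMQ_ref,
  MMQ_alt, MPOS, TLOD, ECNT, POPAF, GERMQ, SEQQ, STRANDQ, ROQ
* 4 derived: SOB (strand-orientation bias of alt-supporting reads),
  orientation cosine (ref-vs-alt orientation-vector similarity),
  ref allele length, alt allele length
* 3 variant-class one-hot: SNV / INS / DEL
* 12 substitution-type one-hot: A>C ... T>G (strand-specific; C>T and
  G>A are separate entries, as cytosine-deamination damage is
  orientation-specific)

Missing annotations carry NaN plus a per-entry imputed flag; the
:class:`FeatureScaler` fills them with training-set medians and z-scores
the numeric block, leaving the one-hot block untouched.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variants import VariantCall

#: the 12 ordered single-nucleotide substitutions
SUBSTITUTION_TYPES: Tuple[str, ...] = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

_NUMERIC_NAMES = (
    "DP", "AD_ref", "AD_alt", "AF",
    "F1R2_ref", "F1R2_alt", "F2R1_ref", "F2R1_alt",
    "MBQ_ref", "MBQ_alt", "MFRL_ref", "MFRL_alt",
    "MMQ_ref", "MMQ_alt", "MPOS", "TLOD", "ECNT", "POPAF",
    "GERMQ", "SEQQ", "STRANDQ", "ROQ",
    "SOB", "orientation_cosine", "ref_len", "alt_len",
)
_ONEHOT_NAMES = ("is_SNV", "is_INS", "is_DEL") + tuple(
    f"sub_{s.replace('>', '_')}" for s in SUBSTITUTION_TYPES
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names bound to the classifier's input width."""

    names: Tuple[str, ...] = _NUMERIC_NAMES + _ONEHOT_NAMES
    version: str = "v1"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def onehot_mask(self) -> np.ndarray:
        """True for entries that are one-hot indicators (never scaled)."""
        return np.array([n.startswith(("is_", "sub_")) for n in self.names])

    @property
    def fingerprint(self) -> str:
        payload = "\n".join(self.names).encode() + b"|" + self.version.encode()
        return hashlib.sha256(payload).hexdigest()[:16]


DEFAULT_SCHEMA = FeatureSchema()


@dataclass
class FeatureVector:
    values: np.ndarray
    imputed: np.ndarray  # bool flags: entry was missing in the call

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)


def compute_maf(call: VariantCall) -> float:
    """Mutation allele frequency: alt depth over informative depth."""
    if call.ad_ref is None or call.ad_alt is None:
        raise ValueError(f"allele depths missing at {call.key}")
    denom = call.ad_ref + call.ad_alt
    if denom == 0:
        raise ValueError(f"zero allele-depth sum at {call.key}; a called variant needs support")
    return call.ad_alt / denom


def compute_sob(f1r2_alt: int, f2r1_alt: int) -> float:
    """Strand-orientation-bias score of alt-supporting reads.

    |F1R2 - F2R1| / (F1R2 + F2R1): 0 for balanced orientations, 1 when all
    alt support comes from a single pair orientation (the deamination-
    artifact signature).  NaN when the alt allele has no orientation-
    resolved support.
    """
    if f1r2_alt < 0 or f2r1_alt < 0:
        raise ValueError("orientation counts must be >= 0")
    total = f1r2_alt + f2r1_alt
    if total == 0:
        return math.nan
    return abs(f1r2_alt - f2r1_alt) / total


def compute_orientation_cosine(
    ref_counts: Tuple[int, int], alt_counts: Tuple[int, int]
) -> float:
    """Cosine similarity between ref and alt (F1R2, F2R1) count vectors.

    1 means the alt allele's orientation profile mirrors the reference
    allele's (as expected for a real variant); values far below 1 indicate
    orientation-specific damage.  NaN when either vector is all-zero.
    """
    r = np.asarray(ref_counts, dtype=float)
    a = np.asarray(alt_counts, dtype=float)
    if (r < 0).any() or (a < 0).any():
        raise ValueError("orientation counts must be >= 0")
    nr, na = np.linalg.norm(r), np.linalg.norm(a)
    if nr == 0.0 or na == 0.0:
        return math.nan
    return float(np.dot(r, a) / (nr * na))


def classify_substitution(ref: str, alt: str) -> str:
    """Classify an allele pair into the 12 SNV types, INS, DEL or COMPLEX."""
    if not ref or not alt:
        raise ValueError("alleles must be nonempty")
    if set(ref) - set("ACGT") or set(alt) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in {ref!r}>{alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        return f"{ref}>{alt}"
    if len(alt) > len(ref):
        return "INS"
    if len(alt) < len(ref):
        return "DEL"
    return "COMPLEX"


def build_feature_vector(
    call: VariantCall, schema: FeatureSchema = DEFAULT_SCHEMA
) -> FeatureVector:
    """Compute the predictor vector for one call.

    A pure function of (call, schema).  Entries whose source annotation is
    absent (or undefined, e.g. SOB with zero orientation-resolved alt
    support) hold NaN with the imputed flag set; the scaler resolves them
    against training-set medians.
    """
    if len(schema) != len(DEFAULT_SCHEMA):
        raise ValueError(f"schema must have {len(DEFAULT_SCHEMA)} entries, got {len(schema)}")
    k = call.key
    ad_sum = (
        None
        if call.ad_ref is None or call.ad_alt is None
        else call.ad_ref + call.ad_alt
    )
    af = None if not ad_sum else call.ad_alt / ad_sum
    sob = (
        math.nan
        if call.f1r2_alt is None or call.f2r1_alt is None
        else compute_sob(call.f1r2_alt, call.f2r1_alt)
    )
    cos = (
        math.nan
        if None in (call.f1r2_ref, call.f2r1_ref, call.f1r2_alt, call.f2r1_alt)
        else compute_orientation_cosine(
            (call.f1r2_ref, call.f2r1_ref), (call.f1r2_alt, call.f2r1_alt)
        )
    )
    numeric = {
        "DP": call.depth, "AD_ref": call.ad_ref, "AD_alt": call.ad_alt, "AF": af,
        "F1R2_ref": call.f1r2_ref, "F1R2_alt": call.f1r2_alt,
        "F2R1_ref": call.f2r1_ref, "F2R1_alt": call.f2r1_alt,
        "MBQ_ref": call.mbq_ref, "MBQ_alt": call.mbq_alt,
        "MFRL_ref": call.mfrl_ref, "MFRL_alt": call.mfrl_alt,
        "MMQ_ref": call.mmq_ref, "MMQ_alt": call.mmq_alt,
        "MPOS": call.mpos, "TLOD": call.tlod, "ECNT": call.ecnt, "POPAF": call.popaf,
        "GERMQ": call.germq, "SEQQ": call.seqq, "STRANDQ": call.strandq, "ROQ": call.roq,
        "SOB": sob, "orientation_cosine": cos,
        "ref_len": len(k.ref), "alt_len": len(k.alt),
    }
    sub = classify_substitution(k.ref, k.alt)
    # variant class by length rule so the one-hot block always sums to 1
    if len(k.ref) == len(k.alt):
        vclass = "is_SNV"
    elif len(k.alt) > len(k.ref):
        vclass = "is_INS"
    else:
        vclass = "is_DEL"
    values = np.empty(len(schema))
    imputed = np.zeros(len(schema), dtype=bool)
    for i, name in enumerate(schema.names):
        if name in numeric:
            v = numeric[name]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                values[i] = math.nan
                imputed[i] = True
            else:
                values[i] = float(v)
        elif name.startswith("is_"):
            values[i] = 1.0 if name == vclass else 0.0
        else:  # sub_X_Y flags; COMPLEX keeps all twelve at 0
            values[i] = 1.0 if name == f"sub_{sub.replace('>', '_')}" else 0.0
    return FeatureVector(values, imputed)


def featurize_calls(
    calls: Sequence[VariantCall], schema: FeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """Stack per-call feature vectors into an (n, 41) matrix (NaN = missing)."""
    if not calls:
        return np.empty((0, len(schema)))
    return np.vstack([build_feature_vector(c, schema).values for c in calls])


class FeatureScaler:
    """Median imputation plus per-feature z-scoring, fit on training data only.

    One-hot entries pass through unchanged; numeric features are imputed
    with the training median and standardised with training mean/sd.
    Constant features map to 0.
    """

    def __init__(self, schema: FeatureSchema = DEFAULT_SCHEMA):
        self.schema = schema

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("scaler requires a nonempty 2-D training matrix")
        if X.shape[1] != len(self.schema):
            raise ValueError(f"expected {len(self.schema)} features, got {X.shape[1]}")
        onehot = self.schema.onehot_mask
        with np.errstate(all="ignore"):
            med = np.nanmedian(X, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        filled = np.where(np.isnan(X), med, X)
        mean = filled.mean(axis=0)
        sd = filled.std(axis=0)
        self.median_ = np.where(onehot, 0.0, med)
        self.mean_ = np.where(onehot, 0.0, mean)
        self.scale_ = np.where(onehot | (sd == 0.0), 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise ValueError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        one = X.ndim == 1
        if one:
            X = X[None, :]
        filled = np.where(np.isnan(X), self.median_, X)
        out = np.where(
            self.schema.onehot_mask, filled, (filled - self.mean_) / self.scale_
        )
        return out[0] if one else out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_scaler(train_vectors: np.ndarray, schema: FeatureSchema = DEFAULT_SCHEMA) -> FeatureScaler:
    return FeatureScaler(schema).fit(np.asarray(train_vectors, dtype=float))


def apply_scaler(scaler: FeatureScaler, vectors: np.ndarray) -> np.ndarray:
    return scaler.transform(vectors)


def feature_table(
    calls: Sequence[VariantCall],
    schema: FeatureSchema = DEFAULT_SCHEMA,
    sample_id: str = "",
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Export a tab-ready table: key columns + schema columns (+ label)."""
    X = featurize_calls(calls, schema)
    df = pd.DataFrame(X, columns=list(schema.names))
    df.insert(0, "alt", [c.key.alt for c in calls])
    df.insert(0, "ref", [c.key.ref for c in calls])
    df.insert(0, "pos", [c.key.pos for c in calls])
    df.insert(0, "chrom", [c.key.chrom for c in calls])
    df.insert(0, "sample_id", sample_id)
    if labels is not None:
        df["label"] = list(labels)
    return df
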