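"""Table readers/writers, control-variant filtering, and the fixture generator.

All tables are tab-separated with a header row and '.' for missing values.
Coordinates are 1-based inclusive. The fixture generator emits a complete
synthetic study — control variants, unlabeled population variants, feature
matrices, domain intervals — with a ground-truth manifest (true priors,
class-conditional families) so that every recovery test runs without any
external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrators import ScoreSet
from .simulate import sample_family

__all__ = [
    "VariantRecord",
    "read_variant_table",
    "write_variant_table",
    "filter_controls",
    "FixtureConfig",
    "GeneConfig",
    "generate_fixture",
]

MISSING = "."


@dataclass
class VariantRecord:
    gene: str
    chrom: str = MISSING
    pos: int | None = None
    ref: str = MISSING
    alt: str = MISSING
    protein_pos: int | None = None
    label: str = "unlabeled"  # P/LP, B/LB, VUS, unlabeled
    review_stars: int = 0
    allele_freq: float | None = None
    splice_score: float | None = None
    score: float | None = None

    @property
    def is_snv(self):
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != MISSING


_COLUMNS = [
    "gene", "chrom", "pos", "ref", "alt", "protein_pos", "label",
    "review_stars", "allele_freq", "splice_score", "score",
]


def write_variant_table(records, path):
    rows = []
    for r in records:
        rows.append(
            {
                c: (MISSING if getattr(r, c) is None else getattr(r, c))
                for c in _COLUMNS
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def _opt(v, cast):
    if pd.isna(v) or v == MISSING:
        return None
    return cast(v)


def read_variant_table(path):
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={"chrom": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            VariantRecord(
                gene=str(row["gene"]),
                chrom=str(row.get("chrom", MISSING)),
                pos=_opt(row.get("pos"), int),
                ref=str(row.get("ref", MISSING)) if pd.notna(row.get("ref")) else MISSING,
                alt=str(row.get("alt", MISSING)) if pd.notna(row.get("alt")) else MISSING,
                protein_pos=_opt(row.get("protein_pos"), int),
                label=str(row.get("label", "unlabeled")),
                review_stars=int(row.get("review_stars", 0) or 0),
                allele_freq=_opt(row.get("allele_freq"), float),
                splice_score=_opt(row.get("splice_score"), float),
                score=_opt(row.get("score"), float),
            )
        )
    return out


def filter_controls(records, training_exclusion=(), af_max=0.01,
                    splice_max=0.2, min_stars=1):
    """Control-variant filtering.

    Keeps missense SNVs with review stars >= 1, allele frequency < 0.01
    (missing frequency retained), splice-impact score < 0.2 (missing
    retained), and not on the predictor-training exclusion list. Genes
    without any surviving P/LP record are dropped entirely (missense must be
    an established disease mechanism for the gene). Returns
    ``(records, n_skipped)``.
    """
    exclusion = set(training_exclusion)
    kept, skipped = [], 0
    for r in records:
        key = (r.gene, r.chrom, r.pos, r.ref, r.alt)
        if not r.is_snv:
            skipped += 1
            continue
        if r.review_stars < min_stars:
            skipped += 1
            continue
        if r.allele_freq is not None and r.allele_freq >= af_max:
            skipped += 1
            continue
        if r.splice_score is not None and r.splice_score >= splice_max:
            skipped += 1
            continue
        if key in exclusion:
            skipped += 1
            continue
        kept.append(r)
    genes_with_plp = {r.gene for r in kept if r.label == "P/LP"}
    final = [r for r in kept if r.gene in genes_with_plp]
    skipped += len(kept) - len(final)
    return final, skipped


@dataclass
class GeneConfig:
    """Ground-truth description of one synthetic gene."""

    gene: str
    prior: float
    family_P: str = "beta"
    params_P: tuple = (8.0, 2.0)
    family_B: str = "beta"
    params_B: tuple = (2.0, 8.0)
    n_p: int = 50
    n_b: int = 50
    n_unlabeled: int = 500
    n_domains: int = 2
    protein_length: int = 500
    feature_dim: int = 4
    feature_separation: float = 3.0


@dataclass
class FixtureConfig:
    genes: list = field(default_factory=list)
    seed: int = 0

    def validate(self):
        problems = []
        for g in self.genes:
            if not 0 < g.prior < 1:
                problems.append(f"{g.gene}: prior out of (0,1)")
            if g.n_p < 1 or g.n_b < 1:
                problems.append(f"{g.gene}: control counts must be positive")
        if problems:
            raise ValueError("invalid fixture config: " + "; ".join(problems))


def generate_fixture(config, seed=None):
    """Emit a synthetic study as in-memory tables plus a ground-truth manifest.

    Returns a dict with per-gene :class:`ScoreSet`s, variant records, feature
    matrices for prior estimation, domain intervals, and the manifest of
    generating parameters.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    study = {"score_sets": {}, "records": [], "features": {}, "domains": [],
             "manifest": {"seed": seed, "genes": {}}}
    for g in config.genes:
        path = sample_family(g.family_P, g.params_P, g.n_p, rng)
        ben = sample_family(g.family_B, g.params_B, g.n_b, rng)
        n_hidden = rng.binomial(g.n_unlabeled, g.prior)
        unl = np.concatenate(
            [
                sample_family(g.family_P, g.params_P, n_hidden, rng),
                sample_family(g.family_B, g.params_B, g.n_unlabeled - n_hidden, rng),
            ]
        )
        rng.shuffle(unl)
        study["score_sets"][g.gene] = ScoreSet(
            pathogenic_scores=path, benign_scores=ben,
            unlabeled_scores=unl, unit_id=g.gene,
        )
        # Gaussian class features with configurable separation: positives sit
        # at +delta on every axis, negatives at 0; unlabeled mixes per prior.
        delta = g.feature_separation
        feat_p = rng.normal(delta, 1.0, size=(g.n_p, g.feature_dim))
        hidden = rng.random(g.n_unlabeled) < g.prior
        feat_u = rng.normal(0.0, 1.0, size=(g.n_unlabeled, g.feature_dim))
        feat_u[hidden] += delta
        study["features"][g.gene] = {
            "P": feat_p, "U": feat_u, "hidden_positive": hidden,
        }
        # evenly spaced non-overlapping domains over the protein
        span = g.protein_length // max(g.n_domains, 1)
        for d in range(g.n_domains):
            start = d * span + 1
            end = min((d + 1) * span - 10, g.protein_length)
            study["domains"].append(
                {"gene": g.gene, "start": start, "end": end,
                 "domain_id": f"{g.gene}_D{d}"}
            )
        for label, scores in (("P/LP", path), ("B/LB", ben), ("unlabeled", unl)):
            for s in scores:
                study["records"].append(
                    VariantRecord(
                        gene=g.gene,
                        protein_pos=int(rng.integers(1, g.protein_length + 1)),
                        label=label,
                        review_stars=2 if label != "unlabeled" else 0,
                        score=float(s),
                    )
                )
        study["manifest"]["genes"][g.gene] = {
            "prior": g.prior,
            "family_P": g.family_P, "params_P": list(g.params_P),
            "family_B": g.family_B, "params_B": list(g.params_B),
            "n_hidden_positive": int(hidden.sum()),
        }
    return study


def write_manifest(manifest, path):
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
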