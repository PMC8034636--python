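"""Enrichment of co-complex pairs in functional standards, feature profiling
of complex members, and contact-level profile-similarity comparisons.

The central quantity is the fold enrichment: the fraction of co-complex pairs
found in a standard divided by the fraction of background pairs found in it,
both computed after restricting to the standard's tested universe. Its
significance comes from a two-sided Fisher exact test on the induced 2x2
table. Member-vs-background feature comparisons use median z-scores
(normalised by the background median and standard deviation) with two-sided
Mann-Whitney U tests for numeric features, and fold enrichment with Fisher
tests for binary flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ComplexDataset
from .pairs import Pair, PairSet, background_pairs, cocomplex_pairs, pair

__all__ = [
    "EnrichmentResult",
    "FeatureProfile",
    "read_feature_table",
    "fisher_exact_2x2",
    "standard_enrichment",
    "feature_profile",
    "relative_difference",
    "relative_difference_comparison",
    "read_similarity_table",
    "average_allele_similarities",
    "contact_similarity_comparison",
    "mannwhitney_two_sided",
]


@dataclass
class EnrichmentResult:
    """Fold enrichment of one pair group over another within a standard."""

    fraction_cocomplex: float
    fraction_background: float
    fold: float
    p_value: float
    contingency: tuple[tuple[int, int], tuple[int, int]]

    def as_dict(self) -> dict:
        return {
            "fraction_cocomplex": self.fraction_cocomplex,
            "fraction_background": self.fraction_background,
            "fold": self.fold,
            "p_value": self.p_value,
            "contingency": [list(r) for r in self.contingency],
        }


@dataclass
class FeatureProfile:
    """Per-feature member-vs-background summary."""

    numeric: dict[str, dict] = field(default_factory=dict)  # median_z, p_value, n
    binary: dict[str, dict] = field(default_factory=dict)  # fold, p_value, contingency


def read_feature_table(path, sidecar=None) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a wide per-protein feature TSV (first column: protein id).

    ``sidecar`` is an optional YAML file declaring column kinds
    (``feature_name: numeric|binary``); undeclared columns are inferred.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    kinds: dict[str, str] = {}
    if sidecar is not None:
        import yaml

        with open(sidecar, encoding="utf-8") as fh:
            kinds = yaml.safe_load(fh) or {}
        bad = {k: v for k, v in kinds.items() if v not in ("numeric", "binary")}
        if bad:
            raise ValueError(f"unknown feature kinds: {bad}")
    return df, kinds


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns the sample odds ratio ``ad/bc`` (may be ``inf``) and the two-sided
    p-value under the probability-mass convention: the sum of hypergeometric
    probabilities of all tables, with the observed margins, no more likely
    than the observed one.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be nonnegative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("fisher_exact_2x2 requires positive margins")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def standard_enrichment(
    cocomplex: PairSet,
    background: PairSet,
    standard: PairSet,
    universe: set[Pair] | PairSet,
) -> EnrichmentResult:
    """Enrichment of co-complex over background pairs within a functional standard.

    Both groups are first restricted to the tested universe (pairs with
    functional data); fractions are then the share of each restricted group
    found in the standard, the fold their ratio, and the p-value a two-sided
    Fisher exact test on the 2x2 table (in standard / not) x (co-complex /
    background).
    """
    if cocomplex.pairs & background.pairs:
        raise ValueError("cocomplex and background pair sets overlap")
    uni = universe.pairs if isinstance(universe, PairSet) else set(universe)
    std = standard.pairs & uni
    co = cocomplex.pairs & uni
    bg = background.pairs & uni
    if not co:
        raise ValueError("no co-complex pairs in the tested universe")
    if not bg:
        raise ValueError("no background pairs in the tested universe")
    a = len(co & std)
    b = len(co) - a
    c = len(bg & std)
    d = len(bg) - c
    frac_co = a / len(co)
    frac_bg = c / len(bg)
    fold = frac_co / frac_bg if frac_bg > 0 else math.inf
    if a + c == 0 or b + d == 0:
        p = 1.0  # standard covers none or all of the universe: uninformative
    else:
        _, p = fisher_exact_2x2(((a, b), (c, d)))
    return EnrichmentResult(frac_co, frac_bg, fold, p, ((a, b), (c, d)))


def feature_profile(
    features: pd.DataFrame,
    members: set[str],
    background: set[str],
    kinds: dict[str, str] | None = None,
    exact_threshold: int = 25,
) -> FeatureProfile:
    """Profile complex members against non-members over a feature panel.

    ``features`` is a wide table indexed by protein id, one column per
    feature. ``kinds`` maps column -> "numeric" | "binary"; boolean columns
    default to binary, the rest to numeric. Numeric features are z-scored
    against the *background* median and sample standard deviation; the median
    z over members is reported with a two-sided Mann-Whitney U p-value.
    Binary features report the member/background fold enrichment with a
    two-sided Fisher exact p. Missing values are excluded per feature; a
    feature with zero background spread is skipped with a warning.
    """
    if members & background:
        raise ValueError("member and background protein sets overlap")
    kinds = kinds or {}
    profile = FeatureProfile()
    for col in features.columns:
        kind = kinds.get(
            col, "binary" if features[col].dropna().isin([0, 1, True, False]).all() else "numeric"
        )
        series = features[col].dropna()
        mem = series[series.index.isin(members)]
        bg = series[series.index.isin(background)]
        if mem.empty or bg.empty:
            warnings.warn(f"feature {col!r}: no data in one group, skipped")
            continue
        if kind == "numeric":
            sd = float(bg.std(ddof=1))
            if not math.isfinite(sd) or sd == 0:
                warnings.warn(f"feature {col!r}: zero background spread, skipped")
                continue
            med = float(bg.median())
            z = (mem.to_numpy(dtype=float) - med) / sd
            _, p = mannwhitney_two_sided(
                mem.to_numpy(dtype=float), bg.to_numpy(dtype=float),
                exact_threshold=exact_threshold,
            )
            profile.numeric[col] = {
                "median_z": float(np.median(z)),
                "p_value": p,
                "n_members": int(mem.size),
                "n_background": int(bg.size),
            }
        else:
            a = int(mem.astype(bool).sum())
            b = int(mem.size - a)
            c = int(bg.astype(bool).sum())
            d = int(bg.size - c)
            frac_m = a / mem.size
            frac_b = c / bg.size
            fold = frac_m / frac_b if frac_b > 0 else math.inf
            try:
                _, p = fisher_exact_2x2(((a, b), (c, d)))
            except ValueError:
                warnings.warn(f"feature {col!r}: degenerate margin, skipped")
                continue
            profile.binary[col] = {
                "fold": fold,
                "p_value": p,
                "contingency": [[a, b], [c, d]],
            }
    return profile


def relative_difference(
    pairs: PairSet, values: dict[str, float]
) -> dict[Pair, float]:
    """Per-pair relative difference (MAX - MIN) / MAX of a nonnegative measure.

    0 means the two proteins have identical values, 1 maximal disparity.
    Pairs with a missing value are excluded; pairs whose larger value is 0 are
    excluded with a warning. Scale-invariant: multiplying all values by a
    positive constant leaves scores unchanged.
    """
    out: dict[Pair, float] = {}
    n_zero = 0
    for p in pairs.pairs:
        a, b = p
        if a not in values or b not in values:
            continue
        va, vb = values[a], values[b]
        if va < 0 or vb < 0:
            raise ValueError(f"negative value for pair {p}")
        hi, lo = max(va, vb), min(va, vb)
        if hi == 0:
            n_zero += 1
            continue
        out[p] = (hi - lo) / hi
    if n_zero:
        warnings.warn(f"{n_zero} pairs excluded: both values zero")
    return out


def relative_difference_comparison(
    cocomplex: PairSet,
    background: PairSet,
    values: dict[str, float],
    exact_threshold: int = 25,
) -> dict:
    """Compare relative-difference distributions of co-complex vs background pairs."""
    rd_co = relative_difference(cocomplex, values)
    rd_bg = relative_difference(background, values)
    if not rd_co or not rd_bg:
        raise ValueError("no scorable pairs in one of the groups")
    a = np.fromiter(rd_co.values(), dtype=float)
    b = np.fromiter(rd_bg.values(), dtype=float)
    u, p = mannwhitney_two_sided(a, b, exact_threshold=exact_threshold)
    return {
        "median_cocomplex": float(np.median(a)),
        "median_background": float(np.median(b)),
        "n_cocomplex": int(a.size),
        "n_background": int(b.size),
        "U": u,
        "p_value": p,
    }


# --------------------------------------------------------------------------
# Contact-level profile-similarity analysis
# --------------------------------------------------------------------------


def read_similarity_table(path) -> pd.DataFrame:
    """Read a 3-column allele-level similarity TSV.

    Columns: allele tag of gene a, allele tag of gene b, similarity. Allele
    tags have the form ``GENE-allele``; the part before the first ``-`` is the
    gene.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["allele_a", "allele_b", "similarity"],
        dtype={"allele_a": str, "allele_b": str, "similarity": float},
    )
    if not np.isfinite(df["similarity"]).all():
        raise ValueError("similarity values must be finite")
    return df


def average_allele_similarities(sims: pd.DataFrame) -> dict[Pair, float]:
    """Collapse allele-level similarity rows to gene pairs by unweighted mean."""
    genes_a = sims["allele_a"].str.split("-", n=1).str[0]
    genes_b = sims["allele_b"].str.split("-", n=1).str[0]
    acc: dict[Pair, list[float]] = {}
    for ga, gb, s in zip(genes_a, genes_b, sims["similarity"]):
        if ga == gb:
            continue  # self interactions are ignored
        acc.setdefault(pair(ga, gb), []).append(float(s))
    return {p: sum(v) / len(v) for p, v in acc.items()}


def contact_similarity_comparison(
    ds: ComplexDataset,
    sims: pd.DataFrame | dict[Pair, float],
    min_size: int = 3,
    exact_threshold: int = 25,
) -> dict:
    """Compare profile similarity of direct vs indirect contacts vs background.

    Complexes of size >= ``min_size`` carrying both kinds of information (at
    least one annotated direct contact and at least one co-member pair not in
    contact) are selected. Pairs are classified as *direct* (annotated
    contacts), *indirect* (same complex, not in contact) or *background*
    (members of different complexes of the selected subset); a pair that is
    direct in any selected complex is direct overall, and indirect beats
    background. Allele-level similarities are averaged to gene pairs first.
    Returns the three similarity distributions and all pairwise two-sided
    Mann-Whitney p-values.
    """
    if isinstance(sims, pd.DataFrame):
        sim_by_pair = average_allele_similarities(sims)
    else:
        sim_by_pair = dict(sims)

    from .io import ComplexDataset as _CD

    selected = []
    for rec in ds.records:
        if rec.size < min_size or not rec.contacts:
            continue
        direct_here = {pair(*sorted(c)) for c in rec.contacts if len(c) == 2}
        all_here = set(
            cocomplex_pairs(_CD("tmp", [rec])).pairs
        )
        if direct_here and (all_here - direct_here):
            selected.append(rec)
    if not selected:
        raise ValueError(
            f"no complex of size >= {min_size} has both direct and indirect contacts"
        )

    sub = _CD(ds.dataset_name + ":contact-informative", selected)
    direct: set[Pair] = set()
    indirect: set[Pair] = set()
    for rec in selected:
        direct |= {pair(*sorted(c)) for c in rec.contacts if len(c) == 2}
    co = cocomplex_pairs(sub).pairs
    indirect = co - direct
    bg = background_pairs(sub).pairs

    def dist(pairs: set[Pair]) -> np.ndarray:
        return np.array(
            sorted(sim_by_pair[p] for p in pairs if p in sim_by_pair), dtype=float
        )

    d, i, b = dist(direct), dist(indirect), dist(bg)
    for name, arr in (("direct", d), ("indirect", i), ("background", b)):
        if arr.size == 0:
            raise ValueError(f"no similarity data for {name} pairs")
    out = {
        "n_complexes_selected": len(selected),
        "distributions": {"direct": d, "indirect": i, "background": b},
        "medians": {
            "direct": float(np.median(d)),
            "indirect": float(np.median(i)),
            "background": float(np.median(b)),
        },
        "p_values": {},
    }
    for (na, xa), (nb, xb) in (
        (("direct", d), ("indirect", i)),
        (("direct", d), ("background", b)),
        (("indirect", i), ("background", b)),
    ):
        _, p = mannwhitney_two_sided(xa, xb, exact_threshold=exact_threshold)
        out["p_values"][f"{na}_vs_{nb}"] = p
    return out


def mannwhitney_two_sided(
    sample_a, sample_b, exact_threshold: int = 25
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    The exact null distribution is used when both samples are small (each
    size <= ``exact_threshold``) and tie-free; otherwise the normal
    approximation with tie correction and continuity correction. Returns
    ``(U, p)`` where U is the statistic of the first sample. If every value is
    tied across both samples the test is uninformative: p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied across both samples; p = 1")
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size <= exact_threshold and b.size <= exact_threshold:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
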