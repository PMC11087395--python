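"""Per-marker, per-population quality control and allelic-effect statistics.

Implements the published QC vocabulary: the *positive* class is
donor-homozygous, the *negative* class recipient-homozygous; heterozygous
and missing calls are excluded from both classes but counted. FPR is the
fraction of truth-recipient lines whose call is not recipient-homozygous;
FNR the fraction of truth donor-allele carriers whose call lacks the donor
allele. Allelic effects use the Kruskal-Wallis rank test with the
0.05/0.01/0.001 significance tiers; single-marker analysis is a least
squares regression of phenotype on the 0/1/2 genotype coding, and the CRD
(completely randomized design) ANOVA reports CV% = 100 * sqrt(MSE) / mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import HET, HOM_ALT, HOM_REF, MISSING, ValidationError

log = logging.getLogger(__name__)


def germination_percent(emerged: int, planted: int) -> float:
    """Percent germination, reported to 2 decimals."""
    if planted <= 0:
        raise ValidationError("planted must be positive")
    if emerged < 0 or emerged > planted:
        raise ValidationError("emerged must lie in [0, planted]")
    return round(100.0 * emerged / planted, 2)


def significance_tier(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class MarkerQCRecord:
    marker_id: str
    population_id: str
    n_tested: int
    n_negative: int
    n_positive: int
    n_het: int
    n_missing: int
    freq_negative: float
    freq_positive: float
    mean_negative: dict = field(default_factory=dict)
    mean_positive: dict = field(default_factory=dict)
    fpr: float = float("nan")
    fnr: float = float("nan")
    utility_set: frozenset = frozenset()
    kw_H: float = float("nan")
    kw_p: float = float("nan")
    significance: str = "ns"
    r2: float = float("nan")
    smr_p: float = float("nan")
    flags: list = field(default_factory=list)


def allele_class_summary(
    calls: pd.Series, phenotypes: pd.DataFrame | None = None, traits: list[str] | None = None
) -> dict:
    """Counts, class frequencies (% of n_tested, 1 decimal) and class means."""
    n_tested = len(calls)
    n_negative = int((calls == HOM_REF).sum())
    n_positive = int((calls == HOM_ALT).sum())
    n_het = int((calls == HET).sum())
    n_missing = int((calls == MISSING).sum())
    assert n_negative + n_positive + n_het + n_missing == n_tested
    out = dict(
        n_tested=n_tested,
        n_negative=n_negative,
        n_positive=n_positive,
        n_het=n_het,
        n_missing=n_missing,
        freq_negative=round(100.0 * n_negative / n_tested, 1) if n_tested else float("nan"),
        freq_positive=round(100.0 * n_positive / n_tested, 1) if n_tested else float("nan"),
        mean_negative={},
        mean_positive={},
        flags=[],
    )
    if phenotypes is not None:
        traits = traits or list(phenotypes.columns)
        neg_idx = calls.index[calls == HOM_REF]
        pos_idx = calls.index[calls == HOM_ALT]
        for trait in traits:
            for label, idx in (("mean_negative", neg_idx), ("mean_positive", pos_idx)):
                if len(idx) == 0:
                    out[label][trait] = float("nan")
                    flag = f"empty_{label.split('_')[1]}_class"
                    if flag not in out["flags"]:
                        out["flags"].append(flag)
                else:
                    out[label][trait] = float(phenotypes.loc[idx, trait].mean())
    return out


def false_positive_rate(
    calls: pd.Series, truth: pd.Series, missing_counts: bool = True
) -> float:
    """Fraction of truth-recipient lines called as anything but recipient.

    ``missing_counts`` (default on) counts missing calls as discordant.
    Undefined (NaN) when no truth-recipient lines exist.
    """
    recip = truth == HOM_REF
    n = int(recip.sum())
    if n == 0:
        log.debug("false_positive_rate: no truth-recipient lines, undefined")
        return float("nan")
    c = calls[recip]
    if missing_counts:
        bad = (c != HOM_REF).sum()
    else:
        bad = ((c != HOM_REF) & (c != MISSING)).sum()
        n = int((c != MISSING).sum())
        if n == 0:
            return float("nan")
    return float(bad / n)


def false_negative_rate(
    calls: pd.Series, truth: pd.Series, missing_counts: bool = True
) -> float:
    """Fraction of truth donor-allele carriers whose call lacks the allele."""
    carrier = (truth == HET) | (truth == HOM_ALT)
    n = int(carrier.sum())
    if n == 0:
        log.debug("false_negative_rate: no truth carrier lines, undefined")
        return float("nan")
    c = calls[carrier]
    lacks = c == HOM_REF
    if missing_counts:
        lacks = lacks | (c == MISSING)
    else:
        n = int((c != MISSING).sum())
        if n == 0:
            return float("nan")
    return float(lacks.sum() / n)


def kasp_utility(
    parental_genotypes: pd.Series, donor_id: str, recipient_ids: list[str]
) -> frozenset:
    """Recipient backgrounds the marker distinguishes from the donor allele.

    Requires opposite homozygotes; het or missing parental calls exclude
    that recipient (conservative).
    """
    d = parental_genotypes[donor_id]
    if d not in (HOM_REF, HOM_ALT):
        return frozenset()
    opposite = HOM_ALT if d == HOM_REF else HOM_REF
    return frozenset(r for r in recipient_ids if parental_genotypes[r] == opposite)


def kruskal_wallis_effect(
    calls: pd.Series, phenotype: pd.Series, include_het: bool = False
) -> tuple[float, float, str]:
    """Kruskal-Wallis H (tie-corrected), chi-square p and significance tier.

    Groups are the negative and positive homozygote classes; the
    heterozygote class joins as a third group when ``include_het``.
    """
    groups = []
    for cls in ([HOM_REF, HOM_ALT] + ([HET] if include_het else [])):
        vals = phenotype[calls.index[calls == cls]].dropna().to_numpy()
        if len(vals):
            groups.append(vals)
    if len(groups) < 2:
        raise ValidationError("need at least 2 non-empty allele classes")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, "ns"
    H, p = stats.kruskal(*groups)
    return float(H), float(p), significance_tier(p)


def kruskal_wallis_permutation_p(
    groups: list[np.ndarray], n_perm: int | None = None, rng=None
) -> float:
    """Exact or Monte-Carlo permutation p-value of the Kruskal-Wallis H.

    With ``n_perm`` None and a small pooled sample, enumerates all
    assignments of pooled values to groups; otherwise samples permutations.
    """
    from itertools import combinations

    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    H_obs = stats.kruskal(*groups)[0]

    def H_of(assign_idx):
        gs, taken = [], np.zeros(len(pooled), bool)
        for idx in assign_idx:
            gs.append(pooled[list(idx)])
            taken[list(idx)] = True
        gs.append(pooled[~taken])
        try:
            return stats.kruskal(*gs)[0]
        except ValueError:  # all identical
            return 0.0

    if n_perm is None and len(groups) == 2 and len(pooled) <= 20:
        count = total = 0
        for idx in combinations(range(len(pooled)), sizes[0]):
            H = H_of([idx])
            total += 1
            if H >= H_obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(rng)
    n_perm = n_perm or 10_000
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        gs, at = [], 0
        for s in sizes:
            gs.append(perm[at : at + s])
            at += s
        try:
            H = stats.kruskal(*gs)[0]
        except ValueError:
            H = 0.0
        if H >= H_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def single_marker_analysis(calls: pd.Series, phenotype: pd.Series) -> tuple[float, float]:
    """Least-squares regression of phenotype on the 0/1/2 genotype coding.

    Returns (r2, p) with p from the F test on (1, n-2) degrees of freedom.
    Missing calls are excluded.
    """
    mask = calls != MISSING
    x = calls[mask].to_numpy(float)
    y = phenotype[calls.index[mask]].to_numpy(float)
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.all(x == x[0]):
        return float("nan"), float("nan")
    if np.all(y == y[0]):
        return 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue)


def anova_crd(observations: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA for a completely randomized design, plus CV%.

    ``observations`` maps genotype label to its replicate values; genotypes
    with fewer than 2 replicates are dropped with a warning. MSE of zero
    flags F as infinite.
    """
    groups = {}
    for name, vals in observations.items():
        vals = np.asarray(vals, float)
        if len(vals) < 2:
            log.warning("anova_crd: genotype %s has <2 replicates, dropped", name)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValidationError("need at least 2 genotypes with >=2 replicates")
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    n_total = len(allv)
    k = len(groups)
    ss_treat = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_treat, df_err = k - 1, n_total - k
    ms_treat = ss_treat / df_treat
    mse = ss_err / df_err
    if mse == 0.0:
        F = float("inf") if ms_treat > 0 else 0.0
        p = 0.0 if ms_treat > 0 else 1.0
        flag = "zero_error_variance" if ms_treat > 0 else "all_equal"
    else:
        F = ms_treat / mse
        p = float(stats.f.sf(F, df_treat, df_err))
        flag = ""
    cv_pct = float("nan") if grand == 0 else 100.0 * math.sqrt(max(mse, 0.0)) / abs(grand)
    return dict(
        ss_treatment=float(ss_treat), ss_error=float(ss_err),
        df_treatment=df_treat, df_error=df_err,
        ms_treatment=float(ms_treat), mse=float(mse),
        F=F, p=p, cv_pct=cv_pct, flag=flag,
    )


def qc_marker(
    marker_id: str,
    population_id: str,
    calls: pd.Series,
    phenotypes: pd.DataFrame | None = None,
    truth: pd.Series | None = None,
    parental_genotypes: pd.Series | None = None,
    donor_id: str | None = None,
    recipient_ids: list[str] | None = None,
    effect_trait: str | None = None,
    include_het: bool = False,
) -> MarkerQCRecord:
    """Assemble the full QC record for one marker in one population."""
    summary = allele_class_summary(calls, phenotypes)
    rec = MarkerQCRecord(
        marker_id=marker_id,
        population_id=population_id,
        n_tested=summary["n_tested"],
        n_negative=summary["n_negative"],
        n_positive=summary["n_positive"],
        n_het=summary["n_het"],
        n_missing=summary["n_missing"],
        freq_negative=summary["freq_negative"],
        freq_positive=summary["freq_positive"],
        mean_negative=summary["mean_negative"],
        mean_positive=summary["mean_positive"],
        flags=summary["flags"],
    )
    if truth is not None:
        rec.fpr = false_positive_rate(calls, truth)
        rec.fnr = false_negative_rate(calls, truth)
    if parental_genotypes is not None and donor_id and recipient_ids:
        rec.utility_set = kasp_utility(parental_genotypes, donor_id, recipient_ids)
    if phenotypes is not None and effect_trait is not None:
        if rec.n_negative and rec.n_positive:
            rec.kw_H, rec.kw_p, rec.significance = kruskal_wallis_effect(
                calls, phenotypes[effect_trait], include_het=include_het
            )
            rec.r2, rec.smr_p = single_marker_analysis(calls, phenotypes[effect_trait])
        else:
            rec.flags.append("effect_test_skipped")
    return rec


def qc_records_to_frame(records: list[MarkerQCRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = dict(
            marker_id=r.marker_id, population_id=r.population_id,
            n_tested=r.n_tested, n_negative=r.n_negative, n_positive=r.n_positive,
            n_het=r.n_het, n_missing=r.n_missing,
            freq_negative=r.freq_negative, freq_positive=r.freq_positive,
            fpr=r.fpr, fnr=r.fnr,
            utility=";".join(sorted(r.utility_set)),
            kw_H=r.kw_H, kw_p=r.kw_p, significance=r.significance,
            r2=r.r2, smr_p=r.smr_p, flags=";".join(r.flags),
        )
        for trait, v in r.mean_negative.items():
            row[f"mean_negative_{trait}"] = v
        for trait, v in r.mean_positive.items():
            row[f"mean_positive_{trait}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
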