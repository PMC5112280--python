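"""Cleavage-site mapping from 5'-RACE clones and qPCR relative expression.

``map_cleavage`` converts clone 5' ends to miRNA-relative coordinates
(position p means the clone's 5' end is the target base paired to miRNA
base p, counted from the miRNA 5' end) and summarises per-position clone
fractions; the 9-11 window fraction captures canonical miRNA-guided
cleavage.  ``ddct`` implements 2^-ddCt relative quantification against a
reference gene and calibrator sample, averaging technical replicates within
each biological replicate.  ``correlate`` reports the descriptive Pearson
(or Spearman) correlation between a miRNA's temporal profile and its
target's relative expression — with four time points no significance is
claimed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, PairingError, UndefinedCorrelationError
from .targets import TargetHit


@dataclass
class CleavageMap:
    target_id: str
    mirna_id: str
    counts: dict[int, int] = field(default_factory=dict)  # miRNA-relative pos
    n_mapped: int = 0
    n_unmapped: int = 0

    @property
    def fractions(self) -> dict[int, float]:
        if self.n_mapped == 0:
            return {}
        return {p: c / self.n_mapped for p, c in sorted(self.counts.items())}

    @property
    def canonical_fraction(self) -> float:
        """Fraction of mapped clones with 5' ends opposite miRNA bases 9-11."""
        if self.n_mapped == 0:
            return 0.0
        return sum(c for p, c in self.counts.items() if 9 <= p <= 11) / self.n_mapped


def map_cleavage(
    clones: pd.DataFrame,
    target_seq: str,
    mirna_seq: str,
    site: TargetHit,
    flank: int = 20,
) -> CleavageMap:
    """Per-position clone counts/fractions within a target's site region.

    ``clones`` needs columns target_id, clone_id, five_prime_pos_1based.
    Clones outside ``site +/- flank`` are tallied as unmapped.
    """
    cm = CleavageMap(target_id=site.transcript_id, mirna_id=site.mirna_id)
    counts: Counter[int] = Counter()
    sub = clones[clones["target_id"] == site.transcript_id]
    for pos1 in sub["five_prime_pos_1based"]:
        pos0 = int(pos1) - 1
        if not (0 <= pos0 < len(target_seq)):
            raise InputError(
                f"clone 5' end {pos1} beyond transcript {site.transcript_id}"
            )
        if pos0 < site.start - flank or pos0 >= site.end + flank:
            cm.n_unmapped += 1
            continue
        p = site.end - pos0  # miRNA base paired to the clone's 5' end
        counts[p] += 1
        cm.n_mapped += 1
    cm.counts = dict(counts)
    return cm


def ddct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression per gene x sample.

    Technical replicates are averaged within each biological replicate;
    dCt = Ct_target - Ct_reference per biological replicate;
    ddCt = dCt_sample - mean dCt_calibrator; relative expression 2^-ddCt is
    summarised as mean +/- SD over biological replicates.
    """
    required = {"gene", "sample", "bio_rep", "tech_rep", "ct"}
    if not required <= set(ct_table.columns):
        raise InputError(f"ct table needs columns {sorted(required)}")
    bio = (
        ct_table.groupby(["gene", "sample", "bio_rep"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    ref = bio[bio["gene"] == reference_gene].set_index(["sample", "bio_rep"])["ct"]
    if ref.empty:
        raise PairingError(f"reference gene {reference_gene!r} absent from the table")
    rows = []
    for gene, gdf in bio[bio["gene"] != reference_gene].groupby("gene", sort=True):
        gdf = gdf.set_index(["sample", "bio_rep"])
        try:
            dct = gdf["ct"] - ref.loc[gdf.index]
        except KeyError as exc:
            raise PairingError(
                f"missing reference measurements for gene {gene!r}: {exc}"
            ) from exc
        cal = dct.loc[calibrator_sample]
        if cal.empty:
            raise PairingError(f"calibrator sample {calibrator_sample!r} missing")
        cal_mean = float(cal.mean())
        for sample, sdf in dct.groupby(level="sample"):
            dd = sdf - cal_mean
            rel = np.power(2.0, -dd)
            rows.append(
                {"gene": gene, "sample": sample,
                 "ddct": float(dd.mean()),
                 "rel_expr": float(rel.mean()),
                 "rel_expr_sd": float(rel.std(ddof=1)) if len(rel) > 1 else 0.0,
                 "n_bio_reps": int(len(rel))}
            )
    return pd.DataFrame(rows)


def correlate(
    mirna_profile,
    target_profile,
    method: str = "pearson",
) -> tuple[float, bool]:
    """Descriptive correlation between two equal-length profiles.

    Returns (r, anti_correlated) where anti_correlated is ``r < 0``.
    """
    x = np.asarray(mirna_profile, dtype=float)
    y = np.asarray(target_profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("profiles must be equal-length 1-D vectors")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance profile")
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return r, r < 0
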