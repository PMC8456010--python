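"""Ecotype-niche concordance scoring and environment classifications.

A phenotype-defined ecotype is judged against an environmental
classification (SDM niches, elevation bands, gradients, or a custom
scheme) by mapping each ecotype to its modal class and counting the
members that fall inside versus outside it.  Two overall-percent
conventions are reported: the exact ratio of correctly classified
populations, and the unweighted mean of the per-ecotype percentages
(rounded to one decimal), which is the convention used in comparable field
reports.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import pandas as pd

from .synthetic_landscape import DEFAULT_BANDS

#: Ecotype and niche membership of the 26 Ethiopian indigenous chicken
#: populations from the field study this pipeline models.  Populations
#: outside their ecotype's modal niche are assigned to a neighbouring niche
#: consistently with the published within/outside split (the specific
#: outside niche was not recorded).
FIELD_STUDY_MEMBERSHIP_CSV = """\
population,ecotype,niche
Fura,1,1
Dalecha,1,1
Birbirsa,1,1
Bengo,1,1
Almeshmesh,1,1
Badu,1,1
Didibe Kistana,1,1
Gazo,1,1
Meket,1,2
Weltane,1,2
Wahelo,1,2
Weledelelo,1,2
Lafinfedo,2,2
Hato,2,2
Melkajebdu,2,2
Arabo,2,3
Burkitu Obora,2,3
Shama,3,3
Parzeit,3,3
Zigh,3,3
Tumi,3,3
Rifenti Chabir,3,3
Sorobo,3,3
Ebech,3,1
Gema,3,1
Gocha,3,1
"""


def field_study_membership() -> pd.DataFrame:
    """The reference 26-population (ecotype, niche) membership table."""
    return pd.read_csv(io.StringIO(FIELD_STUDY_MEMBERSHIP_CSV))


@dataclass
class ConcordanceTable:
    per_ecotype: pd.DataFrame      # ecotype, n, modal class, within, pct...
    overall_count: int
    overall_pct_exact: float       # 100 * total within / n populations
    overall_pct_mean: float        # unweighted mean of rounded per-eco pct
    n_populations: int

    def to_frame(self) -> pd.DataFrame:
        df = self.per_ecotype.copy()
        df.attrs.update(overall_count=self.overall_count,
                        overall_pct_exact=self.overall_pct_exact,
                        overall_pct_mean=self.overall_pct_mean)
        return df


def _align(ecotype_labels: pd.Series, class_labels: pd.Series):
    eco = pd.Series(ecotype_labels)
    cls = pd.Series(class_labels)
    common = eco.index.intersection(cls.index)
    if len(common) == 0 or len(common) != len(eco) or len(common) != len(cls):
        raise ValueError("ecotype and class labels must cover the same "
                         "populations")
    return eco.loc[common], cls.loc[common]


def modal_match(ecotype_labels: pd.Series,
                class_labels: pd.Series) -> pd.DataFrame:
    """Map each ecotype to its most frequent class.

    Ties break toward the lower class index and are flagged.
    """
    eco, cls = _align(ecotype_labels, class_labels)
    rows = []
    for e in sorted(eco.unique()):
        counts = cls[eco == e].value_counts()
        top = counts.max()
        winners = sorted(counts.index[counts == top])
        rows.append({"ecotype": e, "modal_class": winners[0],
                     "tie": len(winners) > 1})
    return pd.DataFrame(rows).set_index("ecotype")


def concordance_table(ecotype_labels: pd.Series,
                      class_labels: pd.Series) -> ConcordanceTable:
    """Within/outside counts and percentages per ecotype plus overall.

    A population is "correctly classified" when its class equals its
    ecotype's modal class; the overall count is the sum of the per-ecotype
    within counts.
    """
    eco, cls = _align(ecotype_labels, class_labels)
    modal = modal_match(eco, cls)
    rows = []
    for e in sorted(eco.unique()):
        members = cls[eco == e]
        within = int((members == modal.loc[e, "modal_class"]).sum())
        n = len(members)
        rows.append({"ecotype": e, "n_members": n,
                     "modal_class": modal.loc[e, "modal_class"],
                     "within": within, "outside": n - within,
                     "pct_within": round(100.0 * within / n, 1),
                     "tie": bool(modal.loc[e, "tie"])})
    per = pd.DataFrame(rows).set_index("ecotype")
    total_within = int(per["within"].sum())
    n_pop = int(per["n_members"].sum())
    pct_exact = round(100.0 * total_within / n_pop, 1)
    pct_mean = round(float(per["pct_within"].mean()), 1)
    return ConcordanceTable(per, total_within, pct_exact, pct_mean, n_pop)


def classify_environment(sites: pd.DataFrame, scheme: str = "elevation_bands",
                         bands=DEFAULT_BANDS,
                         custom: pd.Series | None = None) -> pd.Series:
    """Class labels per population under an environment scheme.

    ``elevation_bands``: band index of the site elevation (intervals
    closed on the left, open on the right; out-of-band sites get label 0
    with a warning).  ``gradient``: the gradient id.  ``custom``: a
    user-provided population -> label mapping.
    """
    idx = sites["population_id"]
    if scheme == "elevation_bands":
        def band_of(e):
            for i, (lo, hi) in enumerate(bands, start=1):
                if lo <= e < hi:
                    return i
            return 0
        lab = sites["elevation"].map(band_of)
        if (lab == 0).any():
            warnings.warn("some sites fall outside every elevation band; "
                          "labelled 0 (unclassified)")
        return pd.Series(lab.to_numpy(), index=idx, name="class")
    if scheme == "gradient":
        return pd.Series(sites["gradient"].to_numpy(), index=idx,
                         name="class")
    if scheme == "custom":
        if custom is None:
            raise ValueError("custom scheme needs a mapping")
        return pd.Series(idx.map(custom).to_numpy(), index=idx,
                         name="class")
    raise ValueError(f"unknown scheme {scheme!r}")


def compare_classifications(ecotype_labels: pd.Series,
                            schemes: dict[str, pd.Series]) -> pd.DataFrame:
    """Concordance per scheme, ranked by the exact overall percentage."""
    if not schemes:
        raise ValueError("need at least one scheme")
    rows = []
    for name, labels in schemes.items():
        ct = concordance_table(ecotype_labels, labels)
        row = {"scheme": name, "n_classes": len(set(labels)),
               "overall_count": ct.overall_count,
               "overall_pct_exact": ct.overall_pct_exact,
               "overall_pct_mean": ct.overall_pct_mean}
        for e in ct.per_ecotype.index:
            row[f"within_eco{e}"] = ct.per_ecotype.loc[e, "within"]
            row[f"pct_eco{e}"] = ct.per_ecotype.loc[e, "pct_within"]
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("overall_pct_exact",
                                         ascending=False)
    return out.reset_index(drop=True)
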