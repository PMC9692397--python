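"""Response-type classification of four-condition expression profiles.

Each gene measured under CTRL, T3 (triiodothyronine), CORT (corticosterone)
and T3+CORT cotreatment is reduced to a z-profile: the four condition means
standardized to mean 0 and (population) SD 1.  Three letters describe the
effect of each treatment relative to control -- "u" (up), "d" (down) or "n"
(no effect) at threshold ``tau_call`` -- and a fourth letter describes the
crosstalk between the two hormones, assigned by a decision tree on the
distances between the cotreatment and each single-hormone condition in
z-space (threshold ``t``):

* ``N`` -- no crosstalk: the cotreatment is explained by the single
  hormones (or their sum) within threshold.
* ``P`` -- potentiation: both hormones act in the same direction and the
  cotreatment exceeds their additive effect by more than ``t``.
* ``a`` / ``A`` -- single / mutual antagonism: the cotreatment response is
  diminished or reversed relative to the single-hormone action; uppercase
  when both cotreatment distances exceed ``t``.
* ``s`` / ``S`` -- synergy: the cotreatment amplifies (or creates) a
  response; uppercase when both distances exceed ``t`` (with ``S`` the
  response strictly requires both hormones).

Strict inequalities are used at every threshold; a profile sitting exactly
on a boundary receives the weaker call ("n", "N", lowercase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "DEFAULT_T",
    "DEFAULT_TAU_CALL",
    "CLUSTER_NAMES",
    "CATEGORY_OF_CLUSTER",
    "DegenerateProfileError",
    "UnclassifiableProfileError",
    "ZProfile",
    "ResponseCall",
    "ClusterSummary",
    "z_transform",
    "call_letters",
    "crosstalk_letter",
    "classify_profile",
    "assign_category",
    "summarize",
    "classify_genes",
]

#: Canonical condition order used throughout the package.
CONDITIONS = ("CTRL", "T3", "CORT", "T3CORT")

#: Distance threshold separating "different" from "similar" condition
#: effects in z-space.
DEFAULT_T = 0.9

#: Threshold on z(X) - z(CTRL) for calling a treatment letter u/d/n.
#: Not independently reported for the original analysis; defaults to ``t``.
DEFAULT_TAU_CALL = 0.9

#: The 26 observed response types, in their original cluster order.
CLUSTER_NAMES = (
    "nddN", "nuuN", "dndN", "unuN", "dddN", "uuuN",
    "duna", "nuna", "dnna", "ddna", "dnda", "dnnA",
    "dunA", "udnA", "unnA", "unna", "unua", "uuna",
    "dddP", "uuuP", "nddS", "nuuS", "nndS", "nnuS",
    "dnuA", "nnds",
)

#: Category A-G membership.  A: T3 only; B: CORT only; C: both hormones
#: independently; D: T3-regulated, influenced by CORT; E: CORT-regulated,
#: influenced by T3; F: regulated by both with crosstalk; G: regulated only
#: when both hormones are present.  ``duna`` and ``uuna`` are placed in F
#: (both hormones regulate); they were omitted from the original category
#: table and are flagged in summaries.
CATEGORY_OF_CLUSTER: dict[str, str] = {}
for _cat, _members in (
    ("A", ("dndN", "unuN")),
    ("B", ("nddN", "nuuN")),
    ("C", ("dddN", "uuuN")),
    ("D", ("dnna", "dnda", "dnnA", "unnA", "unna", "unua", "dnuA")),
    ("E", ("nuna", "nddS", "nuuS")),
    ("F", ("ddna", "dunA", "udnA", "dddP", "uuuP", "duna", "uuna")),
    ("G", ("nndS", "nnuS", "nnds")),
):
    for _m in _members:
        CATEGORY_OF_CLUSTER[_m] = _cat

#: Categories that correspond to crosstalk between the two hormones.
CROSSTALK_CATEGORIES = ("D", "E", "F", "G")

#: Clusters assigned to a category by this package rather than the
#: original table (which omits them).
FLAGGED_CLUSTERS = ("duna", "uuna")


class DegenerateProfileError(ValueError):
    """All four condition means are equal; no z-profile exists."""


class UnclassifiableProfileError(ValueError):
    """Letter triple (n, n, n): the gene shows no called response."""


@dataclass(frozen=True)
class ZProfile:
    """Standardized four-condition profile (CTRL, T3, CORT, T3+CORT)."""

    gene_id: str
    z: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.shape != (4,):
            raise ValueError("a z-profile has exactly four values")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite z value")
        if abs(float(z.mean())) > 1e-6 or abs(float(z.std()) - 1.0) > 1e-6:
            raise ValueError(
                "z-profile must have mean 0 and population SD 1; "
                "use z_transform() to build one from condition means"
            )


@dataclass(frozen=True)
class ResponseCall:
    """Full classification of one gene's z-profile."""

    gene_id: str
    letters: tuple[str, str, str]
    delta_t3: float
    delta_cort: float
    delta_tc: float
    d_T: float  #: |z(T3+CORT) - z(T3)|
    d_G: float  #: |z(T3+CORT) - z(CORT)|
    fourth_letter: str
    cluster_name: str
    category: str | None  #: None for patterns outside the 26 observed types

    @property
    def is_crosstalk(self) -> bool:
        return self.fourth_letter != "N"


def z_transform(condition_means: Sequence[float], gene_id: str = "") -> ZProfile:
    """Standardize four condition means to mean 0 / population SD 1.

    Raises :class:`DegenerateProfileError` when the four means are equal
    (within floating-point tolerance relative to their magnitude).
    """
    m = np.asarray(condition_means, dtype=float)
    if m.shape != (4,):
        raise ValueError("expected exactly four condition means")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite condition mean")
    sd = float(m.std())  # population SD (denominator 4)
    scale = max(1.0, float(np.abs(m).max()))
    if sd <= 1e-12 * scale:
        raise DegenerateProfileError(
            f"constant profile for gene {gene_id!r}: {m.tolist()}"
        )
    z = (m - m.mean()) / sd
    return ZProfile(gene_id=gene_id, z=tuple(float(v) for v in z))


def _letter(delta: float, tau_call: float) -> str:
    if delta > tau_call:
        return "u"
    if delta < -tau_call:
        return "d"
    return "n"


def call_letters(
    profile: ZProfile | Sequence[float], tau_call: float = DEFAULT_TAU_CALL
) -> tuple[str, str, str]:
    """u/d/n letters for T3, CORT and T3+CORT versus control.

    A treatment is "u" when z(X) - z(CTRL) > tau_call, "d" when below
    -tau_call, else "n" (boundary values give "n").
    """
    z = profile.z if isinstance(profile, ZProfile) else tuple(profile)
    zc, zt, zg, ztc = z
    return (_letter(zt - zc, tau_call), _letter(zg - zc, tau_call),
            _letter(ztc - zc, tau_call))


def crosstalk_letter(
    profile: ZProfile | Sequence[float],
    letters: tuple[str, str, str] | None = None,
    t: float = DEFAULT_T,
    tau_call: float = DEFAULT_TAU_CALL,
) -> str:
    """Fourth (crosstalk) letter for a profile with a non-(n,n,n) triple.

    The tree branches on the u/d/n pattern of the two single hormones, and
    on the distances d_T = |z(TC) - z(T3)| and d_G = |z(TC) - z(CORT)|
    relative to the threshold ``t``; X below counts how many of the two
    distances exceed ``t``.
    """
    z = profile.z if isinstance(profile, ZProfile) else tuple(profile)
    if letters is None:
        letters = call_letters(z, tau_call)
    zc, zt, zg, ztc = z
    l_t3, l_cort, l_tc = letters
    if letters == ("n", "n", "n"):
        raise UnclassifiableProfileError("no treatment effect was called")

    d1, d2, d3 = zt - zc, zg - zc, ztc - zc
    d_T, d_G = abs(ztc - zt), abs(ztc - zg)
    n_far = int(d_T > t) + int(d_G > t)

    if l_t3 != "n" and l_cort != "n":
        if (d1 > 0) != (d2 > 0):
            # Opposite single-hormone effects: antagonism by construction.
            return "A" if n_far == 2 else "a"
        # Same direction: compare cotreatment with the additive prediction.
        d_add = d1 + d2
        if abs(d3 - d_add) <= t:
            return "N"
        if abs(d3) > abs(d_add):
            return "P"
        return "A" if n_far == 2 else "a"

    if l_t3 != "n" or l_cort != "n":
        # Exactly one hormone has a called effect, H.
        if l_t3 != "n":
            d_h, delta_h = d_T, d1
        else:
            d_h, delta_h = d_G, d2
        if d_h <= t:
            return "N"
        amplified = (d3 > 0) == (delta_h > 0) and abs(d3) >= abs(delta_h)
        if amplified:
            return "S" if n_far == 2 else "s"
        # Diminished or sign-reversed cotreatment response.
        return "A" if n_far == 2 else "a"

    # Neither hormone alone acts, but the cotreatment does: synergy.
    return "S" if n_far == 2 else "s"


def assign_category(cluster_name: str) -> str:
    """Category A-G of one of the 26 observed response types."""
    try:
        return CATEGORY_OF_CLUSTER[cluster_name]
    except KeyError:
        raise KeyError(f"unknown cluster name {cluster_name!r}") from None


def classify_profile(
    profile: ZProfile,
    t: float = DEFAULT_T,
    tau_call: float = DEFAULT_TAU_CALL,
) -> ResponseCall | None:
    """Classify a z-profile; ``None`` when no treatment letter is called.

    Genes whose three deltas all sit within ``tau_call`` are reported as
    unclassified rather than forced into a cluster.
    """
    zc, zt, zg, ztc = profile.z
    letters = call_letters(profile, tau_call)
    if letters == ("n", "n", "n"):
        return None
    fourth = crosstalk_letter(profile, letters, t=t, tau_call=tau_call)
    name = "".join(letters) + fourth
    return ResponseCall(
        gene_id=profile.gene_id,
        letters=letters,
        delta_t3=zt - zc,
        delta_cort=zg - zc,
        delta_tc=ztc - zc,
        d_T=abs(ztc - zt),
        d_G=abs(ztc - zg),
        fourth_letter=fourth,
        cluster_name=name,
        category=CATEGORY_OF_CLUSTER.get(name),
    )


@dataclass
class ClusterSummary:
    """Per-cluster and per-category counts of classified genes."""

    cluster_counts: dict[str, int] = field(default_factory=dict)
    category_counts: dict[str, int] = field(default_factory=dict)
    total: int = 0

    @property
    def category_percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in self.category_counts}
        return {c: 100.0 * n / self.total for c, n in self.category_counts.items()}

    @property
    def crosstalk_total(self) -> int:
        return sum(self.category_counts.get(c, 0) for c in CROSSTALK_CATEGORIES)

    @property
    def crosstalk_percentage(self) -> float:
        return 100.0 * self.crosstalk_total / self.total if self.total else 0.0

    @classmethod
    def from_category_counts(cls, counts: Mapping[str, int]) -> "ClusterSummary":
        """Build a summary from per-category totals alone."""
        cat = {c: int(n) for c, n in counts.items()}
        return cls(cluster_counts={}, category_counts=cat, total=sum(cat.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pct = self.category_percentages
        for cat in sorted(self.category_counts):
            clusters = sorted(
                n for n, c in CATEGORY_OF_CLUSTER.items() if c == cat
            )
            rows.append(
                {
                    "category": cat,
                    "gene_number": self.category_counts[cat],
                    "pct_of_de_genes": round(pct[cat], 2),
                    "clusters": ",".join(clusters),
                }
            )
        return pd.DataFrame(rows)


def summarize(calls: Iterable[ResponseCall]) -> ClusterSummary:
    """Tally classified genes per cluster and per category.

    Calls whose 4-letter pattern lies outside the 26 observed types are
    counted under their own cluster name with category "other".
    """
    cluster_counts: dict[str, int] = {}
    category_counts: dict[str, int] = {}
    total = 0
    for call in calls:
        total += 1
        cluster_counts[call.cluster_name] = cluster_counts.get(call.cluster_name, 0) + 1
        cat = call.category if call.category is not None else "other"
        category_counts[cat] = category_counts.get(cat, 0) + 1
    return ClusterSummary(
        cluster_counts=cluster_counts,
        category_counts=category_counts,
        total=total,
    )


def classify_genes(
    condition_means: pd.DataFrame,
    t: float = DEFAULT_T,
    tau_call: float = DEFAULT_TAU_CALL,
) -> tuple[pd.DataFrame, list[str]]:
    """Classify every row of a genes x 4-condition mean table.

    Parameters
    ----------
    condition_means
        DataFrame indexed by gene id with columns CTRL, T3, CORT, T3CORT
        (means of size-factor-normalized counts).

    Returns
    -------
    calls : DataFrame with one row per classified gene (z values, letters,
        distances, cluster and category).
    unclassified : gene ids skipped because their profile was constant or
        no treatment letter was called.
    """
    missing = [c for c in CONDITIONS if c not in condition_means.columns]
    if missing:
        raise ValueError(f"missing condition columns: {missing}")
    rows = []
    unclassified: list[str] = []
    for gene_id, row in condition_means[list(CONDITIONS)].iterrows():
        try:
            prof = z_transform(row.to_numpy(), gene_id=str(gene_id))
        except DegenerateProfileError:
            unclassified.append(str(gene_id))
            continue
        call = classify_profile(prof, t=t, tau_call=tau_call)
        if call is None:
            unclassified.append(str(gene_id))
            continue
        rows.append(
            {
                "gene_id": call.gene_id,
                "z_ctrl": prof.z[0],
                "z_t3": prof.z[1],
                "z_cort": prof.z[2],
                "z_t3cort": prof.z[3],
                "L_T3": call.letters[0],
                "L_CORT": call.letters[1],
                "L_TC": call.letters[2],
                "d_T": call.d_T,
                "d_G": call.d_G,
                "fourth_letter": call.fourth_letter,
                "cluster": call.cluster_name,
                "category": call.category if call.category is not None else "other",
            }
        )
    columns = [
        "gene_id", "z_ctrl", "z_t3", "z_cort", "z_t3cort",
        "L_T3", "L_CORT", "L_TC", "d_T", "d_G",
        "fourth_letter", "cluster", "category",
    ]
    calls = pd.DataFrame(rows, columns=columns)
    return calls, unclassified
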