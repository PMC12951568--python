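"""Panel-level structure-activity statistics.

Compounds are annotated with structural tags from a controlled
vocabulary (charge, symmetry, steric bulk, rigidity, core type,
substituent position, central atom) and their photodynamic activities
(EC50) compared across structural subgroups.  Because activities in a
diverse panel span several orders of magnitude, group comparisons use
Welch's t test on log10(EC50); following the convention of flagging
fragile comparisons, any test in which either group has only two
members is marked with ``small_group_flag``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .dose_response import EC50Result

__all__ = [
    "CompoundRecord",
    "GroupComparison",
    "TAG_VOCABULARY",
    "parse_tag_query",
    "compare_groups",
    "fold_activity",
]

TAG_VOCABULARY: Dict[str, Tuple[str, ...]] = {
    "charge": ("anionic", "cationic", "neutral", "silicon"),
    "symmetry": ("symmetrical", "unsymmetrical"),
    "bulk": ("bulky", "nonbulky"),
    "rigidity": ("rigid", "flexible"),
    "core": ("Pc", "pyrazine", "pyrido"),
    "position": ("alpha", "beta"),
    # central_atom is free text (Zn, Mg, Al, Si, 2H, ...)
}


@dataclass
class CompoundRecord:
    """One panel row: identity, structural tags, measured endpoints."""

    compound_id: str
    tags: Dict[str, str]
    endpoints: Dict[str, EC50Result] = field(default_factory=dict)  # cell line -> EC50
    phi_delta: Optional[float] = None
    phi_f: Optional[float] = None
    log_p: Optional[float] = None
    lambda_A_nm: Optional[float] = None

    def __post_init__(self) -> None:
        for key, value in self.tags.items():
            allowed = TAG_VOCABULARY.get(key)
            if allowed is not None and value not in allowed:
                raise ValueError(
                    f"{self.compound_id}: tag {key}={value!r} not in vocabulary {allowed}"
                )

    def matches(self, query: Mapping[str, str]) -> bool:
        return all(self.tags.get(k) == v for k, v in query.items())


@dataclass
class GroupComparison:
    group_a: Dict[str, str]
    group_b: Dict[str, str]
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    log10_means: Tuple[float, float]
    small_group_flag: bool


def parse_tag_query(query: str) -> Dict[str, str]:
    """Parse ``"charge=cationic,core=Pc"`` into a tag mapping."""
    out: Dict[str, str] = {}
    for part in query.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed tag query component {part!r}")
        k, v = (s.strip() for s in part.split("=", 1))
        out[k] = v
    if not out:
        raise ValueError("empty tag query")
    return out


def _group_ec50s(
    panel: Sequence[CompoundRecord], query: Mapping[str, str], cell_line: str
) -> np.ndarray:
    vals = [
        rec.endpoints[cell_line].ec50_nM
        for rec in panel
        if rec.matches(query) and cell_line in rec.endpoints
    ]
    return np.asarray(vals, dtype=float)


def compare_groups(
    panel: Sequence[CompoundRecord],
    query_a: Mapping[str, str],
    query_b: Mapping[str, str],
    cell_line: str,
) -> GroupComparison:
    """Welch two-sample t test on log10(EC50) between two tag-defined groups."""
    a = _group_ec50s(panel, query_a, cell_line)
    b = _group_ec50s(panel, query_b, cell_line)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group after filtering; check the tag query")
    if a.size < 2 or b.size < 2:
        raise ValueError("a group with one member has no variance; t test undefined")
    la, lb = np.log10(a), np.log10(b)
    if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and np.isclose(la[0], lb[0]):
        t_stat, p = 0.0, 1.0  # identical degenerate groups
    else:
        t_stat, p = stats.ttest_ind(la, lb, equal_var=False)
    return GroupComparison(
        group_a=dict(query_a),
        group_b=dict(query_b),
        n_a=int(a.size),
        n_b=int(b.size),
        t_statistic=float(t_stat),
        p_value=float(p),
        log10_means=(float(la.mean()), float(lb.mean())),
        small_group_flag=min(a.size, b.size) <= 2,
    )


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjustment for a family of group comparisons."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def fold_activity(
    panel: Sequence[CompoundRecord],
    compound_a: str,
    compound_b: str,
    cell_line: str,
) -> float:
    """EC50 ratio a/b; a fold > 1 means compound b is the more active."""
    by_id = {rec.compound_id: rec for rec in panel}
    try:
        rec_a, rec_b = by_id[compound_a], by_id[compound_b]
    except KeyError as exc:
        raise KeyError(f"compound {exc.args[0]!r} not in panel") from None
    for rec in (rec_a, rec_b):
        if cell_line not in rec.endpoints:
            raise ValueError(f"{rec.compound_id} has no {cell_line} endpoint")
    return rec_a.endpoints[cell_line].ec50_nM / rec_b.endpoints[cell_line].ec50_nM
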