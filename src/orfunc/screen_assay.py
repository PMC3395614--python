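"""Luciferase screen processing: plate normalization, agonist calls, tuning curves.

A screen tests a set of receptors against a diverse odor panel (42 odors in
the reference design) in triplicate at a single concentration. Each well
reports firefly luciferase (the cAMP reporter downstream of receptor
activation) and Renilla luciferase (a constitutive transfection control).
Processing steps:

1. divide firefly by Renilla per well;
2. min-max normalize the ratios within a declared scope (one plate, or the
   set of plates for an ortholog set): (L_N - L_min) / (L_max - L_min);
3. per receptor x odor, a two-tailed t-test against the matched no-odor
   control with Bonferroni correction over the panel (alpha / n_odors);
4. the tuning response is the normalized odor mean minus the normalized
   no-odor mean, so inhibitory odors come out negative and keep their sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NO_ODOR = "no_odor"
VECTOR = "vector"

PLATE_COLUMNS = ["receptor", "odor", "replicate", "firefly", "renilla", "plate_id"]


class PlateError(ValueError):
    """Raised for malformed or degenerate plate data."""


def validate_plate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns and c != "plate_id"]
    if missing:
        raise PlateError(f"plate table missing columns: {missing}")
    if "plate_id" not in df.columns:
        df = df.assign(plate_id="plate1")
    if (df["renilla"] <= 0).any():
        raise PlateError("Renilla luminescence must be > 0 in every well")
    return df


@dataclass
class ScreenMatrix:
    """Normalized screen responses with per-cell statistics and agonist calls.

    ``wells`` is the per-well table (adds ``ratio`` and ``norm`` columns);
    ``summary`` is one row per receptor x odor with mean, SE, n, and, after
    :func:`call_agonists`, the t-test p-value, the significance flag and the
    control-subtracted ``response``. ``scope_record`` documents the L_min and
    L_max actually used, keeping the normalization auditable.
    """

    wells: pd.DataFrame
    summary: pd.DataFrame
    scope: str
    scope_record: pd.DataFrame
    alpha: float | None = None
    n_odors: int | None = None

    def responses(self, receptor: str, odors: list[str] | None = None,
                  zero_nonsignificant: bool = True) -> pd.Series:
        """Tuning responses for one receptor, indexed by odor.

        The display convention zeroes cells that did not pass the Bonferroni
        gate; significant cells keep their sign (inhibition stays negative).
        """
        sub = self.summary[self.summary["receptor"] == receptor]
        sub = sub[~sub["odor"].isin([NO_ODOR, VECTOR])]
        s = sub.set_index("odor")["response"].copy()
        if zero_nonsignificant:
            if "significant" not in sub.columns:
                raise PlateError("run call_agonists before requesting a display copy")
            sig = sub.set_index("odor")["significant"]
            s[~sig] = 0.0
        if odors is not None:
            s = s.reindex(odors)
        return s


def normalize_plate(measurements: pd.DataFrame, scope: str = "plate_set") -> ScreenMatrix:
    """Min-max normalize firefly/Renilla ratios within the declared scope.

    scope="plate_set" uses one (L_min, L_max) across all wells passed in;
    scope="plate" normalizes each plate_id independently.
    """
    if scope not in ("plate", "plate_set"):
        raise ValueError(f"scope must be 'plate' or 'plate_set', got {scope!r}")
    df = validate_plate(measurements.copy())
    df["ratio"] = df["firefly"] / df["renilla"]

    records = []
    if scope == "plate_set":
        groups = [("all_plates", df.index)]
    else:
        groups = [(pid, idx) for pid, idx in df.groupby("plate_id").groups.items()]
    df["norm"] = np.nan
    for unit, idx in groups:
        lmin = df.loc[idx, "ratio"].min()
        lmax = df.loc[idx, "ratio"].max()
        if lmax == lmin:
            raise PlateError(f"degenerate normalization scope {unit!r}: L_max == L_min")
        df.loc[idx, "norm"] = (df.loc[idx, "ratio"] - lmin) / (lmax - lmin)
        records.append({"scope_unit": unit, "l_min": lmin, "l_max": lmax})

    summary = (
        df.groupby(["receptor", "odor"])["norm"]
        .agg(mean_response="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    return ScreenMatrix(df, summary, scope, pd.DataFrame(records))


def call_agonists(matrix: ScreenMatrix, n_odors: int = 42, alpha: float = 0.05,
                  equal_var: bool = True) -> ScreenMatrix:
    """Bonferroni-gated agonist calls against the no-odor control.

    Per receptor, each odor's replicate normalized values are compared to the
    no-odor replicates by a two-tailed two-sample t-test at alpha / n_odors
    (pooled variance by default). The significance flag is kept for negative
    (inhibitory) responses as well. The tuning ``response`` column is the
    normalized odor mean minus the normalized no-odor mean.
    """
    threshold = alpha / n_odors
    wells = matrix.wells
    rows = []
    for receptor, sub in wells.groupby("receptor"):
        control = sub.loc[sub["odor"] == NO_ODOR, "norm"].to_numpy()
        if control.size == 0:
            raise PlateError(f"receptor {receptor!r} has no no-odor control wells")
        if control.size < 2:
            raise PlateError(f"receptor {receptor!r} needs >= 2 no-odor replicates")
        for odor, cell in sub.groupby("odor"):
            vals = cell["norm"].to_numpy()
            if odor == NO_ODOR:
                p = 1.0
            elif vals.size < 2:
                raise PlateError(f"cell {receptor}/{odor} needs >= 2 replicates")
            else:
                p = float(stats.ttest_ind(vals, control, equal_var=equal_var).pvalue)
                if np.isnan(p):  # zero pooled variance with equal means
                    p = 1.0
            rows.append(
                {
                    "receptor": receptor,
                    "odor": odor,
                    "mean_response": vals.mean(),
                    "se": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                    "n": vals.size,
                    "p_value": p,
                    "significant": bool(p < threshold) and odor != NO_ODOR,
                    "response": vals.mean() - control.mean(),
                }
            )
    matrix.summary = pd.DataFrame(rows)
    matrix.alpha = alpha
    matrix.n_odors = n_odors
    return matrix


@dataclass
class TuningCurve:
    """Center-out ordered odor responses for an ortholog set.

    Odors are ranked by the reference receptor's response; the best ligand
    sits at the center and successive ranks alternate outward (rightward
    first). Every member of the set shares the reference ordering, which is
    what makes the profiles visually comparable.
    """

    reference: str
    odors: list[str]          # odor label per display position, left to right
    responses: pd.DataFrame   # receptors x ordered odors

    def position_of(self, odor: str) -> int:
        return self.odors.index(odor)


def center_out_order(ranked: list[str]) -> list[str]:
    """Place rank 1 centrally, then alternate right, left, right, ...

    For n items the center index is (n - 1) // 2, which leaves enough room on
    the right for the first outward step.
    """
    n = len(ranked)
    out: list[str | None] = [None] * n
    center = (n - 1) // 2
    out[center] = ranked[0]
    offset = 0
    side_right = True
    for item in ranked[1:]:
        if side_right:
            offset += 1
            out[center + offset] = item
        else:
            out[center - offset] = item
        side_right = not side_right
    return out  # type: ignore[return-value]


def order_tuning_curve(matrix: ScreenMatrix, reference: str,
                       variants: list[str] | None = None) -> TuningCurve:
    """Build center-out tuning curves from an agonist-called screen.

    Ranking uses the reference receptor's display responses (non-significant
    cells zeroed), descending; ties break by odor label so the ordering is
    deterministic. Variant receptors reuse the reference ordering.
    """
    ref = matrix.responses(reference)
    if ref.empty:
        raise PlateError(f"reference receptor {reference!r} not in screen")
    ranked = sorted(ref.index, key=lambda o: (-ref[o], o))
    ordered = center_out_order(ranked)
    members = [reference] + (variants or [])
    table = pd.DataFrame(
        {r: matrix.responses(r, odors=ordered) for r in members}
    ).T
    table = table[ordered]
    return TuningCurve(reference, ordered, table)
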