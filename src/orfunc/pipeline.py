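"""Stage orchestration: each analysis stage as a function over files.

Stages read the text formats in :mod:`orfunc.io`, run the corresponding
library module, and write TSV outputs whose header comment carries the
digest of a JSON run manifest (tool version, seeds, input digests, output
paths). Running the stages one by one or through :func:`run_all` gives
identical outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import comparative_stats as cs
from . import io as oio
from .dose_response import agonist_gate, classify_pair, fit_3pl
from .odor_space import DescriptorMatrix, select_panel
from .screen_assay import call_agonists, normalize_plate, order_tuning_curve
from .seq_evol import (
    CodingSequencePair,
    ResiduePositionSet,
    grantham_distance,
    jukes_cantor_distance,
    nei_gojobori_omega,
)


def _digest_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written alongside every stage's outputs."""

    stage: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> digest
    outputs: list = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest_file(path)

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "timestamp"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / f"manifest_{self.stage}.json"
        with open(path, "w") as fh:
            json.dump({**self.__dict__, "digest": self.digest()}, fh, indent=2,
                      default=str)
        return path


def run_seq_stage(fasta_path, pairs: list[tuple[str, str]], out_dir,
                  positions: ResiduePositionSet | None = None) -> pd.DataFrame:
    """Pairwise sequence metrics for the listed id pairs -> pairwise_metrics.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = oio.read_fasta(fasta_path)
    manifest = RunManifest("seq", config={"pairs": pairs})
    manifest.add_input(fasta_path)
    rows = []
    for id_a, id_b in pairs:
        for name in (id_a, id_b):
            if name not in seqs:
                raise KeyError(f"pair member {name!r} missing from {fasta_path}")
        pair = CodingSequencePair.from_nucleotides(id_a, seqs[id_a], id_b, seqs[id_b])
        omega = nei_gojobori_omega(pair)
        row = {
            "id_a": id_a,
            "id_b": id_b,
            "jc": jukes_cantor_distance(pair),
            "grantham_orf": grantham_distance(pair),
            "grantham_22aa": (
                grantham_distance(pair, positions) if positions is not None else np.nan
            ),
            "dN": omega.dN,
            "dS": omega.dS,
            "omega": omega.omega,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    out = out_dir / "pairwise_metrics.tsv"
    manifest.outputs.append(str(out))
    oio.write_tsv(out, table, manifest.digest())
    manifest.write(out_dir)
    return table


def run_screen_stage(plate_csv, out_dir, scope: str = "plate_set",
                     n_odors: int | None = None, alpha: float = 0.05,
                     references: dict[str, list[str]] | None = None):
    """Normalize + agonist-call a screen -> screen.tsv (+ tuning TSVs).

    ``references`` maps a reference receptor to its variant receptors; each
    entry yields a tuning_<reference>.tsv with the shared center-out order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plate = oio.read_plate_csv(plate_csv)
    odor_names = set(plate["odor"]) - {"no_odor", "vector"}
    n_odors = n_odors or len(odor_names)
    manifest = RunManifest("screen", config={"scope": scope, "alpha": alpha,
                                             "n_odors": n_odors})
    manifest.add_input(plate_csv)
    screen = call_agonists(normalize_plate(plate, scope=scope),
                           n_odors=n_odors, alpha=alpha)
    out = out_dir / "screen.tsv"
    manifest.outputs.append(str(out))
    oio.write_tsv(out, screen.summary, manifest.digest())
    for ref, variants in (references or {}).items():
        tc = order_tuning_curve(screen, ref, variants)
        ttab = tc.responses.reset_index(names="receptor")
        tout = out_dir / f"tuning_{ref}.tsv"
        manifest.outputs.append(str(tout))
        oio.write_tsv(tout, ttab, manifest.digest())
    manifest.write(out_dir)
    return screen


def run_dr_stage(dose_csv, out_dir, pairs: list[tuple[str, str]] | None = None,
                 alpha: float = 0.05):
    """Fit, gate and pairwise-classify dose-response data.

    Writes fits.tsv (per receptor x odor), comparisons.tsv (per pair) and
    classification_summary.tsv (label fractions). ``pairs`` lists receptor
    label pairs to compare; default: all within-odor combinations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    datasets, controls = oio.read_dose_response_csv(dose_csv)
    manifest = RunManifest("dose_response", config={"alpha": alpha, "pairs": pairs})
    manifest.add_input(dose_csv)

    fit_rows = []
    fits = {}
    gates = {}
    for (receptor, odor), ds in datasets.items():
        fit = fit_3pl(ds)
        fits[(receptor, odor)] = fit
        control = controls.get(odor)
        gate = agonist_gate(fit, ds, control, alpha) if control is not None else None
        gates[(receptor, odor)] = gate
        fit_rows.append({
            "receptor": receptor, "odor": odor,
            "logEC50": fit.logec50, "se_logEC50": fit.se_logec50,
            "bottom": fit.bottom, "top": fit.top, "span": fit.span,
            "ss": fit.ss, "df": fit.df,
            "agonist": gate.agonist if gate else np.nan,
            "reasons": ";".join(gate.reasons) if gate else "",
        })
    fit_table = pd.DataFrame(fit_rows)

    by_odor: dict[str, list[str]] = {}
    for receptor, odor in datasets:
        by_odor.setdefault(odor, []).append(receptor)
    if pairs is None:
        pair_list = [
            (odor, a, b)
            for odor, receptors in by_odor.items()
            for a, b in itertools.combinations(sorted(receptors), 2)
        ]
    else:
        pair_list = [
            (odor, a, b)
            for odor, receptors in by_odor.items()
            for a, b in pairs
            if a in receptors and b in receptors
        ]
    cmp_rows = []
    for odor, a, b in pair_list:
        control = controls.get(odor)
        cls = classify_pair(datasets[(a, odor)], datasets[(b, odor)],
                            control, control, alpha=alpha)
        cmp_rows.append({
            "odor": odor, "receptor_a": a, "receptor_b": b,
            "logEC50_a": cls.fit_a.logec50 if cls.fit_a else np.nan,
            "logEC50_b": cls.fit_b.logec50 if cls.fit_b else np.nan,
            "span_a": cls.fit_a.span if cls.fit_a else np.nan,
            "span_b": cls.fit_b.span if cls.fit_b else np.nan,
            "F": cls.extra_ss.F if cls.extra_ss else np.nan,
            "df_num": cls.extra_ss.df_num if cls.extra_ss else np.nan,
            "df_den": cls.extra_ss.df_den if cls.extra_ss else np.nan,
            "p_value": cls.extra_ss.p if cls.extra_ss else np.nan,
            "label": cls.label,
        })
    cmp_table = pd.DataFrame(cmp_rows)
    if len(cmp_table):
        frac = cmp_table["label"].value_counts(normalize=True)
        summary = pd.DataFrame({"label": frac.index, "fraction": frac.values})
    else:
        summary = pd.DataFrame(columns=["label", "fraction"])

    for name, tab in [("fits.tsv", fit_table), ("comparisons.tsv", cmp_table),
                      ("classification_summary.tsv", summary)]:
        out = out_dir / name
        manifest.outputs.append(str(out))
        oio.write_tsv(out, tab, manifest.digest())
    manifest.write(out_dir)
    return fit_table, cmp_table, summary


def run_compare_stage(seq_tsv, screen_tsv, out_dir, min_responsive: int = 3):
    """Sequence-vs-function report: per-pair table + Spearman correlations.

    Functional distance is recomputed from the screen TSV display responses
    (non-significant cells zeroed) for each pair in the sequence-metric
    table; each sequence metric is then rank-correlated with 1 - R over the
    included pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq = oio.read_tsv(seq_tsv)
    screen = oio.read_tsv(screen_tsv)
    if seq.empty:
        raise ValueError(f"empty sequence-metric table {seq_tsv}")
    manifest = RunManifest("compare", config={"min_responsive": min_responsive})
    manifest.add_input(seq_tsv)
    manifest.add_input(screen_tsv)

    screen = screen[~screen["odor"].isin(["no_odor", "vector"])]
    display = screen.assign(
        display=np.where(screen["significant"], screen["response"], 0.0)
    ).pivot_table(index="receptor", columns="odor", values="display")

    rows = []
    for _, row in seq.iterrows():
        ra = display.loc[row["id_a"]].to_numpy()
        rb = display.loc[row["id_b"]].to_numpy()
        rec = cs.functional_distance(ra, rb, min_responsive=min_responsive,
                                     id_a=row["id_a"], id_b=row["id_b"])
        out_row = dict(row)
        out_row.update(r=rec.r, functional_distance=rec.distance,
                       n_responsive_a=rec.n_responsive_a,
                       n_responsive_b=rec.n_responsive_b, included=rec.included)
        rows.append(out_row)
    pair_table = pd.DataFrame(rows)

    corr_rows = []
    included = pair_table[pair_table["included"]
                          & pair_table["functional_distance"].notna()]
    for metric in ("jc", "grantham_orf", "grantham_22aa", "omega"):
        if metric not in included.columns or included[metric].notna().sum() < 4:
            continue
        rc = cs.rank_correlation(included[metric], included["functional_distance"])
        corr_rows.append({"metric": metric, "r_s": rc.rs, "p": rc.p, "n": rc.n})
    corr_table = pd.DataFrame(corr_rows)

    for name, tab in [("seq_func_pairs.tsv", pair_table),
                      ("correlations.tsv", corr_table)]:
        out = out_dir / name
        manifest.outputs.append(str(out))
        oio.write_tsv(out, tab, manifest.digest())
    manifest.write(out_dir)
    return pair_table, corr_table


def run_panel_stage(descriptor_csv, out_dir, k: int = 42, seed: int = 0):
    """k-means odor-panel selection -> panel.tsv (+ PCA projection)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dm = DescriptorMatrix.from_frame(pd.read_csv(descriptor_csv))
    manifest = RunManifest("panel", seed=seed, config={"k": k})
    manifest.add_input(descriptor_csv)
    panel = select_panel(dm, k=k, seed=seed)
    out = out_dir / "panel.tsv"
    manifest.outputs.append(str(out))
    oio.write_tsv(out, panel.table, manifest.digest())
    manifest.write(out_dir)
    return panel


def run_all(fasta_path, pairs, plate_csv, out_dir, dose_csv=None,
            positions=None, min_responsive: int = 3, alpha: float = 0.05):
    """Full pipeline: sequence metrics, screen, (optional) dose-response, compare."""
    out_dir = Path(out_dir)
    seq_table = run_seq_stage(fasta_path, pairs, out_dir, positions)
    run_screen_stage(plate_csv, out_dir, alpha=alpha)
    if dose_csv is not None:
        run_dr_stage(dose_csv, out_dir, alpha=alpha)
    pair_table, corr_table = run_compare_stage(
        out_dir / "pairwise_metrics.tsv", out_dir / "screen.tsv", out_dir,
        min_responsive=min_responsive,
    )
    return seq_table, pair_table, corr_table
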