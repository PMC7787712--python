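"""Model/Results interface tying the full analysis together.

:class:`ThermoregModel` wraps a table of field observations (one row per
crab) and :meth:`ThermoregModel.fit` runs the complete analysis:

1. monthly body-temperature comparisons across the four sex-by-size
   classes (Kruskal–Wallis with Dunn's Bonferroni post hoc);
2. per-sex tests of whether size changes the thermal response, on both
   analyses — thermoregulation capacity (Tb - S) against surface
   temperature, and against burrow cooling capacity (B - S) — by
   sequential ANCOVA and by its permutational analogue (PERMANOVA);
3. per-group regressions yielding the burrow use efficiency E_B, the
   no-refuge offset b = T̂e - S, and the onset temperature T_reg.

The returned :class:`ThermoregResults` carries every fitted object, a
``summary()`` table, TSV/JSON serialisation, and diagnostic plots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data import (Month, ObservationRecord, Sex, SizeClass, ValidationReport,
                   read_records, records_to_frame)
from .linmod import AncovaResult, LinearFit, Transform, ancova, fit_ols
from .nonparam import (DunnResult, KruskalResult, PermanovaResult,
                       dunn_posthoc, kruskal_wallis, permanova)
from .thermoreg import (GroupContrast, ThermoregEstimates, estimates_from_fits,
                        group_contrast)

__all__ = ["ThermoregModel", "ThermoregResults"]

GROUP_ORDER = (SizeClass.small_female, SizeClass.large_female,
               SizeClass.small_male, SizeClass.large_male)
MONTH_ORDER = (Month.march, Month.may, Month.august, Month.october)

ESTIMATE_COLUMNS = ("group", "n", "e_b", "e_b_se", "b_offset", "b_offset_se",
                    "m", "c", "surface_at_onset", "t_reg", "t_reg_upper")


class ThermoregModel:
    """Thermoregulation analysis model over a frame of field records.

    The frame must carry columns ``sex``, ``carapace_width_mm``,
    ``body_temp_c``, ``surface_temp_c``, ``burrow_temp_c`` (NaN where the
    burrow was not probed) and ``month``; ``size_class`` and the derived
    axes coordinates are computed if absent.
    """

    def __init__(self, frame: pd.DataFrame,
                 validation: ValidationReport | None = None):
        if frame is None or len(frame) == 0:
            raise ValueError("no records to analyse")
        df = frame.copy()
        if "thermoreg_capacity_c" not in df.columns:
            df["thermoreg_capacity_c"] = df["body_temp_c"] - df["surface_temp_c"]
        if "cooling_capacity_c" not in df.columns:
            df["cooling_capacity_c"] = df["burrow_temp_c"] - df["surface_temp_c"]
        if "size_class" not in df.columns:
            from .data import assign_size_class
            df["size_class"] = [
                assign_size_class(s, w).value
                for s, w in zip(df["sex"], df["carapace_width_mm"])]
        self.frame = df
        self.validation = validation

    # ---------------------------------------------------------------- ctors
    @classmethod
    def from_records(cls, records: Sequence[ObservationRecord]
                     ) -> "ThermoregModel":
        return cls(records_to_frame(records))

    @classmethod
    def from_csv(cls, path, schema: Mapping[str, str] | None = None
                 ) -> "ThermoregModel":
        records, report = read_records(path, schema=schema)
        if not records:
            raise ValueError(
                f"no valid records in {path}: {report.n_rejected} rejected")
        return cls(records_to_frame(records), validation=report)

    @classmethod
    def from_synthetic(cls, config=None, seed: int | None = None
                       ) -> "ThermoregModel":
        from .simulate import generate_dataset
        records, sidecar = generate_dataset(config, seed=seed)
        model = cls.from_records(records)
        model.ground_truth = sidecar
        return model

    # ------------------------------------------------------------------ fit
    def fit(self, n_perm: int = 999, seed: int = 0,
            transform: Transform | str = Transform.none,
            size_as: str = "class",
            months: Sequence[str] | None = None) -> "ThermoregResults":
        """Run the full analysis.

        Parameters
        ----------
        n_perm, seed
            Permutation count and seed for the PERMANOVA tables.
        transform
            Dependent-variable transform for the ANCOVA hypothesis tests
            (never for parameter estimation).
        size_as
            ``"class"`` treats size as the dichotomous small/large factor,
            ``"continuous"`` uses carapace width directly.
        months
            Optional month filter (names; ``September`` aliases October).
        """
        df = self.frame
        if months:
            keep = {Month.parse(m).value for m in months}
            df = df[df["month"].isin(keep)]
            if len(df) == 0:
                raise ValueError(f"no records in months {sorted(keep)}")
        known = df[df["size_class"] != SizeClass.out_of_range.value]

        monthly = _monthly_comparisons(known)
        capacity_fits, axes_fits, axes_notes = _per_group_fits(known)
        estimates = {
            g: estimates_from_fits(g, axes_fits[g], capacity_fits[g])
            for g in capacity_fits if g in axes_fits
        }
        contrasts = _size_contrasts(estimates)
        ancovas, permanovas = _per_sex_tests(
            known, transform=Transform(transform), size_as=size_as,
            n_perm=n_perm, seed=seed)

        return ThermoregResults(
            model=self, frame=df,
            n_input=len(self.frame), n_used=len(known),
            n_out_of_range=int(len(df) - len(known)),
            n_with_burrow=int(known["cooling_capacity_c"].notna().sum()),
            monthly_kruskal={m: r[0] for m, r in monthly.items()},
            monthly_dunn={m: r[1] for m, r in monthly.items()},
            monthly_groups={m: r[2] for m, r in monthly.items()},
            capacity_fits=capacity_fits, axes_fits=axes_fits,
            axes_notes=axes_notes, estimates=estimates, contrasts=contrasts,
            ancova_tables=ancovas, permanova_tables=permanovas,
            n_perm=n_perm, seed=seed, transform=Transform(transform),
            size_as=size_as,
        )


def _frame_to_records(df: pd.DataFrame):
    for row in df.itertuples(index=False):
        b = getattr(row, "burrow_temp_c", None)
        if b is not None and pd.isna(b):
            b = None
        yield ObservationRecord(
            crab_id=str(getattr(row, "crab_id", "")),
            sex=Sex(row.sex), carapace_width_mm=float(row.carapace_width_mm),
            body_temp_c=float(row.body_temp_c),
            surface_temp_c=float(row.surface_temp_c),
            burrow_temp_c=None if b is None else float(b),
            month=Month.parse(row.month),
            site=str(getattr(row, "site", "")))


def _monthly_comparisons(df: pd.DataFrame):
    out = {}
    for month in MONTH_ORDER:
        sub = df[df["month"] == month.value]
        groups, labels = [], []
        for g in GROUP_ORDER:
            vals = sub.loc[sub["size_class"] == g.value, "body_temp_c"].to_numpy()
            if vals.size > 0:
                groups.append(vals)
                labels.append(g.value)
        if len(groups) < 2:
            continue
        kw = kruskal_wallis(groups)
        dunn = dunn_posthoc(groups)
        out[month.value] = (kw, dunn, tuple(labels))
    return out


def _per_group_fits(df: pd.DataFrame):
    capacity_fits: dict[SizeClass, LinearFit] = {}
    axes_fits: dict[SizeClass, LinearFit] = {}
    notes: dict[SizeClass, str] = {}
    for g in GROUP_ORDER:
        sub = df[df["size_class"] == g.value]
        if len(sub) < 3:
            notes[g] = f"not computable: only {len(sub)} records"
            continue
        capacity_fits[g] = fit_ols(sub["surface_temp_c"].to_numpy(),
                                   sub["thermoreg_capacity_c"].to_numpy())
        ax = sub.dropna(subset=["cooling_capacity_c"])
        if len(ax) < 3:
            notes[g] = ("axes analysis not computable: fewer than 3 records "
                        "with a burrow reading")
            continue
        try:
            axes_fits[g] = fit_ols(ax["cooling_capacity_c"].to_numpy(),
                                   ax["thermoreg_capacity_c"].to_numpy())
        except ValueError as e:
            notes[g] = f"axes analysis not computable: {e}"
    return capacity_fits, axes_fits, notes


def _size_contrasts(estimates: Mapping[SizeClass, ThermoregEstimates]):
    pairs = [(SizeClass.small_female, SizeClass.large_female),
             (SizeClass.small_male, SizeClass.large_male)]
    out: dict[str, GroupContrast] = {}
    for a, b in pairs:
        if a in estimates and b in estimates:
            out[f"{a.value}_vs_{b.value}"] = group_contrast(
                estimates[a], estimates[b])
    return out


def _per_sex_tests(df: pd.DataFrame, transform: Transform, size_as: str,
                   n_perm: int, seed: int):
    """ANCOVA and PERMANOVA per sex for both analyses.

    ``capacity_vs_surface`` regresses Tb - S on S; ``axes`` regresses
    Tb - S on B - S (records with a burrow reading only).
    """
    ancovas: dict[str, AncovaResult] = {}
    permanovas: dict[str, PermanovaResult] = {}
    for si, sex in enumerate(Sex):
        sub = df[df["sex"] == sex.value]
        for ai, (analysis, covariate_col, need_burrow) in enumerate([
                ("capacity_vs_surface", "surface_temp_c", False),
                ("axes", "cooling_capacity_c", True)]):
            d = sub.dropna(subset=[covariate_col])
            if size_as == "continuous":
                fac = d["carapace_width_mm"].to_numpy()
            else:
                fac = d["size_class"].to_numpy()
            y = d["thermoreg_capacity_c"].to_numpy()
            cov = d[covariate_col].to_numpy()
            key = f"{sex.value}_{analysis}"
            if len(d) < 8 or np.unique(fac).size < 2:
                continue
            try:
                ancovas[key] = ancova(y, fac, cov, include_interaction=True,
                                      transform=transform)
                permanovas[key] = permanova(
                    y, fac, cov, include_interaction=True, n_perm=n_perm,
                    seed=seed + 13 * si + 7 * ai)
            except ValueError:
                continue
    return ancovas, permanovas


@dataclass
class ThermoregResults:
    """Fitted thermoregulation analysis.

    Attributes mirror the analysis stages; ``estimates`` maps each
    sex-by-size class to its :class:`ThermoregEstimates` (E_B, b, T_reg
    with delta-method standard errors and the provenance fits).
    """

    model: ThermoregModel
    frame: pd.DataFrame
    n_input: int
    n_used: int
    n_out_of_range: int
    n_with_burrow: int
    monthly_kruskal: dict[str, KruskalResult]
    monthly_dunn: dict[str, DunnResult]
    monthly_groups: dict[str, tuple[str, ...]]
    capacity_fits: dict[SizeClass, LinearFit]
    axes_fits: dict[SizeClass, LinearFit]
    axes_notes: dict[SizeClass, str]
    estimates: dict[SizeClass, ThermoregEstimates]
    contrasts: dict[str, GroupContrast]
    ancova_tables: dict[str, AncovaResult]
    permanova_tables: dict[str, PermanovaResult]
    n_perm: int
    seed: int
    transform: Transform
    size_as: str
    extra: dict = field(default_factory=dict)

    # -------------------------------------------------------------- tables
    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for g in GROUP_ORDER:
            if g not in self.estimates:
                continue
            e = self.estimates[g]
            rows.append({
                "group": g.value, "n": e.axes_fit.n,
                "e_b": e.e_b, "e_b_se": e.e_b_se,
                "b_offset": e.b_offset, "b_offset_se": e.b_offset_se,
                "m": e.m, "c": e.c,
                "surface_at_onset": e.surface_at_onset,
                "t_reg": e.t_reg, "t_reg_upper": e.t_reg_upper,
            })
        return pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS))

    def estimates_tsv(self) -> str:
        df = self.estimates_frame().copy()
        for col in df.columns:
            if col not in ("group", "n"):
                df[col] = df[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.2f}")
        return df.to_csv(sep="\t", index=False)

    def implied_sensitivities(self) -> dict[str, float]:
        """dTb/dS = 1 + m per group, from the capacity-vs-surface fits."""
        from .thermoreg import implied_tb_sensitivity
        return {g.value: implied_tb_sensitivity(f)
                for g, f in self.capacity_fits.items()}

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        lines = []
        w = lines.append
        w("Burrow thermoregulation analysis")
        w("=" * 70)
        w(f"records: {self.n_input} input, {self.n_used} in sex-by-size "
          f"classes, {self.n_with_burrow} with burrow reading")
        if self.model.validation is not None:
            v = self.model.validation
            w(f"ingest: {v.n_accepted} accepted, {v.n_rejected} rejected, "
              f"{v.n_flagged} flagged")
        w("")
        w("Thermoregulation estimates per group")
        w("-" * 70)
        w(f"{'group':<14}{'n':>5}{'E_B':>8}{'(se)':>8}{'b=Te-S':>8}"
          f"{'(se)':>8}{'T_reg':>8}{'upper':>8}")
        for g in GROUP_ORDER:
            e = self.estimates.get(g)
            if e is None:
                note = self.axes_notes.get(g, "not computable")
                w(f"{g.value:<14}  {note}")
                continue
            t_reg = "undef" if e.t_reg is None else f"{e.t_reg:8.2f}"
            t_up = "" if e.t_reg_upper is None else f"{e.t_reg_upper:8.2f}"
            w(f"{g.value:<14}{e.axes_fit.n:>5}{e.e_b:>8.2f}"
              f"{e.e_b_se:>8.2f}{e.b_offset:>8.2f}{e.b_offset_se:>8.2f}"
              f"{t_reg:>8}{t_up:>8}")
        w("")
        w("Implied body-temperature sensitivity dTb/dS = 1 + m")
        for g, v in self.implied_sensitivities().items():
            w(f"  {g:<14}{v:6.2f} °C/°C")
        w("")
        w(f"Monthly Kruskal-Wallis on Tb across groups")
        for month, kw in self.monthly_kruskal.items():
            w(f"  {month:<9} H({kw.df}) = {kw.h_statistic:6.2f}, "
              f"p = {kw.p_value:.3f}  (ns={list(kw.group_ns)})")
        w("")
        w(f"Sequential tests (covariate, then size, then interaction); "
          f"size as {self.size_as}; transform {self.transform.value}")
        for key in sorted(self.ancova_tables):
            a = self.ancova_tables[key]
            w(f"  ANCOVA     {key:<28} F_cov={a.f_covariate:8.1f} "
              f"(p={a.p_covariate:.3f})  F_size={a.f_factor:6.2f} "
              f"(p={a.p_factor:.3f})  F_int={a.f_interaction:6.2f} "
              f"(p={a.p_interaction:.3f})")
        for key in sorted(self.permanova_tables):
            p = self.permanova_tables[key]
            w(f"  PERMANOVA  {key:<28} "
              f"F_cov={p.pseudo_f['covariate']:8.1f} "
              f"(p={p.p_perm['covariate']:.3f})  "
              f"F_size={p.pseudo_f['factor']:6.2f} "
              f"(p={p.p_perm['factor']:.3f})  "
              f"F_int={p.pseudo_f['interaction']:6.2f} "
              f"(p={p.p_perm['interaction']:.3f})")
        w("")
        w(f"PERMANOVA: {self.n_perm} permutations, seed {self.seed} "
          f"(p floor {1.0 / (self.n_perm + 1):.3g})")
        return "\n".join(lines)

    # ---------------------------------------------------------------- json
    def to_report_dict(self) -> dict:
        rep = {
            "software": {"package": "burrowtherm", "version": __version__},
            "provenance": {
                "n_input": self.n_input,
                "n_used": self.n_used,
                "n_out_of_range": self.n_out_of_range,
                "n_with_burrow": self.n_with_burrow,
                "n_perm": self.n_perm,
                "seed": self.seed,
                "transform": self.transform.value,
                "size_as": self.size_as,
            },
            "estimates": {g.value: e.to_dict()
                          for g, e in self.estimates.items()},
            "axes_notes": {g.value: n for g, n in self.axes_notes.items()},
            "capacity_fits": {g.value: f.to_dict(g.value)
                              for g, f in self.capacity_fits.items()},
            "axes_fits": {g.value: f.to_dict(g.value)
                          for g, f in self.axes_fits.items()},
            "implied_tb_sensitivity": self.implied_sensitivities(),
            "contrasts": {k: c.to_dict() for k, c in self.contrasts.items()},
            "monthly_kruskal": {m: k.to_dict()
                                for m, k in self.monthly_kruskal.items()},
            "monthly_dunn": {
                m: {"groups": list(self.monthly_groups[m]),
                    "pairs": d.to_dict()}
                for m, d in self.monthly_dunn.items()},
            "ancova": {k: a.to_dict() for k, a in self.ancova_tables.items()},
            "permanova": {k: p.to_dict()
                          for k, p in self.permanova_tables.items()},
        }
        if self.model.validation is not None:
            rep["validation"] = json.loads(self.model.validation.to_json())
        if getattr(self.model, "ground_truth", None) is not None:
            rep["provenance"]["generator_config"] = \
                self.model.ground_truth["config"]
            rep["recovery"] = self.recovery_table()
        return rep

    def recovery_table(self) -> dict | None:
        """Join estimates to generating truth (synthetic runs only).

        For each group, reports the generating (E_B, b, T_reg), the
        full-sample estimates, and onset-conditioned estimates refit on
        the crabs the sidecar marks as thermoregulating — the subset on
        which the single-line estimators are unbiased.
        """
        truth = getattr(self.model, "ground_truth", None)
        if truth is None:
            return None
        from .simulate import onset_conditioned_estimates
        from .data import ObservationRecord
        records = [r for r in _frame_to_records(self.frame)]
        conditioned = onset_conditioned_estimates(records, truth)
        out = {}
        for g in GROUP_ORDER:
            gp = truth["config"]["groups"].get(g.value)
            if gp is None:
                continue
            row = {"true_e_b": gp["e_b"], "true_b_offset": gp["b_offset"],
                   "true_t_reg": gp["t_reg"]}
            if g in self.estimates:
                e = self.estimates[g]
                row["full_sample"] = {"e_b": e.e_b, "b_offset": e.b_offset,
                                      "t_reg": e.t_reg}
            if g in conditioned:
                e = conditioned[g]
                row["onset_conditioned"] = {
                    "e_b": e.e_b, "e_b_se": e.e_b_se,
                    "b_offset": e.b_offset, "b_offset_se": e.b_offset_se,
                    "t_reg": e.t_reg, "t_reg_se": e.t_reg_se}
            out[g.value] = row
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_report_dict(), indent=indent,
                          sort_keys=True, allow_nan=True)

    def save_report(self, out_dir: str | Path, figures: bool = True) -> None:
        """Write estimates.tsv, tests.json, report.json and figures/."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "estimates.tsv").write_text(self.estimates_tsv())
        tests = {
            "monthly_kruskal": {m: k.to_dict()
                                for m, k in self.monthly_kruskal.items()},
            "ancova": {k: a.to_dict() for k, a in self.ancova_tables.items()},
            "permanova": {k: p.to_dict()
                          for k, p in self.permanova_tables.items()},
        }
        (out / "tests.json").write_text(json.dumps(tests, indent=2,
                                                   sort_keys=True))
        (out / "report.json").write_text(self.to_json())
        if figures:
            from . import plotting
            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            plotting.plot_capacity_vs_surface(
                self, path=figdir / "capacity_vs_surface.png")
            plotting.plot_axes(self, path=figdir / "thermoregulation_axes.png")

    # ---------------------------------------------------------------- plots
    def plot_capacity_vs_surface(self, ax=None):
        from . import plotting
        return plotting.plot_capacity_vs_surface(self, ax=ax)

    def plot_axes(self, ax=None):
        from . import plotting
        return plotting.plot_axes(self, ax=ax)
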