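"""Readers/writers for the package's delimited file formats.

Matrices are TSV/CSV with a header row and a leading sample-ID column
(samples x features).  Group membership files are two-column TSVs
(feature<TAB>group).  Missing values are rejected, never imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .groups import GroupStructure
from .solver import Scaler

logger = logging.getLogger("brilliant")

__all__ = [
    "NamedMatrix",
    "read_matrix",
    "write_matrix",
    "align",
    "save_fit",
    "load_fit",
]


@dataclass
class NamedMatrix:
    """Dense numeric matrix with unique row and column names."""

    values: np.ndarray
    row_names: list[str]
    col_names: list[str]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NamedMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            row_names=[str(i) for i in df.index],
            col_names=[str(c) for c in df.columns],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_names, columns=self.col_names)

    @property
    def shape(self):
        return self.values.shape


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path, orientation: str = "samples_by_features") -> NamedMatrix:
    """Load a delimited numeric matrix with header row and ID column.

    ``orientation="features_by_samples"`` transposes after reading so the
    returned matrix is always samples x features.  Ragged rows, non-numeric
    cells, missing values and duplicate IDs raise with context.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table ({err})") from None
    if orientation == "features_by_samples":
        df = df.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    for axis, names in (("sample", df.index), ("feature", df.columns)):
        dup = pd.Index(names)[pd.Index(names).duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicated {axis} ID {dup[0]!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        bad = df.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(bad.isna().to_numpy() & df.notna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"(line {r + 2})"
        ) from None
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"(line {r + 2}); missing data are rejected, not imputed"
        )
    return NamedMatrix.from_frame(df)


def write_matrix(nm, path) -> None:
    """Write a NamedMatrix or DataFrame; floats are written with 17
    significant digits so a read_matrix round-trip is bit-exact."""
    df = nm.to_frame() if isinstance(nm, NamedMatrix) else nm
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def align(X: NamedMatrix, Y: NamedMatrix):
    """Restrict X and Y to their common samples, in X's row order.

    Logs dropped samples; an empty intersection raises.
    """
    common = [s for s in X.row_names if s in set(Y.row_names)]
    if len(common) < 2:
        raise ValueError(
            f"sample overlap between X ({len(X.row_names)}) and Y "
            f"({len(Y.row_names)}) has size {len(common)}; need >= 2"
        )
    dropped_x = len(X.row_names) - len(common)
    dropped_y = len(Y.row_names) - len(common)
    if dropped_x or dropped_y:
        logger.info("align: dropped %d samples from X, %d from Y", dropped_x, dropped_y)
    xf = X.to_frame().loc[common]
    yf = Y.to_frame().loc[common]
    return NamedMatrix.from_frame(xf), NamedMatrix.from_frame(yf)


# ----------------------------------------------------------------------
# fit directory: coefficients + scaling + diagnostics, enough to predict

def save_fit(results, outdir) -> None:
    from .model import BrilliantResults  # local import to avoid cycle

    assert isinstance(results, BrilliantResults)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(results.params, out / "coefficients.tsv")
    write_matrix(results.coef_standardized, out / "B_hat.tsv")
    write_matrix(results.coef_thresholded, out / "B_tilde.tsv")
    m = results.model
    scaling = {
        "x_mean": m.scaler.x_mean.tolist(),
        "x_scale": m.scaler.x_scale.tolist(),
        "y_mean": m.scaler.y_mean.tolist(),
        "x_names": m.x_names,
        "y_names": m.y_names,
    }
    (out / "scaling.json").write_text(json.dumps(scaling))
    f = results.fit
    diag = {
        "lambda1": f.penalties.lambda1,
        "lambda2": f.penalties.lambda2,
        "b_thr": f.penalties.b_thr,
        "sweeps": f.sweeps_run,
        "final_delta": f.final_delta,
        "converged": f.converged,
        "objective_trace": f.objective_trace,
        "precision_source": m.omega.source,
    }
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))


@dataclass
class LoadedFit:
    """Minimal predictor reconstructed from a fit directory."""

    B_tilde: np.ndarray
    B_hat: np.ndarray
    scaler: Scaler
    x_names: list[str]
    y_names: list[str]
    diagnostics: dict

    def predict(self, X: pd.DataFrame, use_threshold: bool = True) -> pd.DataFrame:
        missing = sorted(set(self.x_names) - set(map(str, X.columns)))
        extra = sorted(set(map(str, X.columns)) - set(self.x_names))
        if missing or extra:
            parts = []
            if missing:
                parts.append("missing predictors: " + ", ".join(missing[:10]))
            if extra:
                parts.append("unknown predictors: " + ", ".join(extra[:10]))
            raise ValueError("; ".join(parts))
        Xs = self.scaler.transform_x(X.loc[:, self.x_names].to_numpy(dtype=float))
        B = self.B_tilde if use_threshold else self.B_hat
        return pd.DataFrame(Xs @ B + self.scaler.y_mean, index=X.index,
                            columns=self.y_names)


def load_fit(fitdir) -> LoadedFit:
    fitdir = Path(fitdir)
    scaling = json.loads((fitdir / "scaling.json").read_text())
    diag = json.loads((fitdir / "diagnostics.json").read_text())
    scaler = Scaler(
        x_mean=np.asarray(scaling["x_mean"], dtype=float),
        x_scale=np.asarray(scaling["x_scale"], dtype=float),
        y_mean=np.asarray(scaling["y_mean"], dtype=float),
    )
    bt = read_matrix(fitdir / "B_tilde.tsv")
    bh = read_matrix(fitdir / "B_hat.tsv")
    return LoadedFit(
        B_tilde=bt.values,
        B_hat=bh.values,
        scaler=scaler,
        x_names=scaling["x_names"],
        y_names=scaling["y_names"],
        diagnostics=diag,
    )
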