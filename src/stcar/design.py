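"""Model design matrices from panel covariates, including interactions."""

from __future__ import annotations

import numpy as np

from .synthetic import PanelData

__all__ = ["build_design"]


def _term_column(panel: PanelData, term: str) -> np.ndarray:
    """Resolve one formula term to a (K, T) array.

    A term is a covariate name ("uldi", "green", "coastal", ...) or a
    product of names joined by ":" (e.g. "uldi:coastal"), evaluated
    elementwise so downstream fitting treats it as an ordinary covariate.
    """
    parts = term.split(":")
    col = np.ones((panel.K, panel.T))
    for p in parts:
        col = col * panel.covariate(p.strip())
    return col


def build_design(
    panel: PanelData, terms: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """(K, T, p) design array with an intercept column first.

    Default terms: the urban-expansion measure followed by every panel
    covariate.  Unknown names raise ``KeyError``.
    """
    if terms is None:
        terms = ["uldi"] + list(panel.covariate_names)
    cols = [np.ones((panel.K, panel.T))]
    names = ["intercept"]
    for term in terms:
        cols.append(_term_column(panel, term))
        names.append(term)
    return np.stack(cols, axis=2), names
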