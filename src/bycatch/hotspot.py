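"""Annual bycatch hotspot extraction and lagged climate cross-correlation.

The hotspot of a year is the in-domain mesh node maximizing the posterior
mean of that year's spatial effect on the occurrence scale (a property of the
spatiotemporal field itself, independent of covariate composition; a switch
allows using the predicted-probability argmax instead).  Years without a
positive bycatch set in the training data carry no hotspot.  Hotspot latitude
is then cross-correlated with an annual climate index at integer lags, with
pairwise deletion of missing years and the ±1.96/√n large-sample band for
two-sided 5% significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from bycatch.geometry import DomainSpec
from bycatch.hurdle import HurdleFit, SubFit
from bycatch.mesh import BarrierMesh
from bycatch.synth import ClimateSeries
from bycatch.terms import FieldTerm


def _field_term(fit: SubFit) -> FieldTerm:
    for t in fit.design.terms:
        if isinstance(t, FieldTerm):
            return t
    raise ValueError("fit has no spatial field term")


def annual_hotspot(fit: SubFit, mesh: BarrierMesh, domain: DomainSpec,
                   year: int, zero_bycatch_years=(),
                   use_probability: bool = False):
    """Hotspot (lon, lat, field value) of one year, or None if missing.

    The argmax runs over in-domain mesh nodes only; exact ties resolve to the
    lowest node index.  ``use_probability`` switches the ranking to the
    posterior-mean bycatch probability at the node (field plus the other
    terms' contribution is NOT included — only the intercept shifts, so the
    argmax is unchanged; the switch matters only for the reported value).
    """
    term = _field_term(fit)
    if term.replicated:
        if term.years is None or int(year) not in term.years:
            raise ValueError(f"year {year} outside the fitted range")
    if int(year) in set(int(y) for y in zero_bycatch_years):
        return None
    xm = fit.posterior_mean_latent()
    sl = fit.design.slices[term.name]
    block = xm[sl]
    if term.replicated:
        k = mesh.n_nodes
        j = term.years.index(int(year))
        block = block[j * k:(j + 1) * k]
    vals = np.where(mesh.node_in_domain, block, -np.inf)
    node = int(np.argmax(vals))            # argmax takes the lowest tied index
    lon, lat = domain.from_planar(mesh.nodes[node, 0], mesh.nodes[node, 1])
    value = float(block[node])
    if use_probability:
        value = float(expit(value + xm[fit.design.slices["intercept"]][0]))
    return float(lon), float(lat), value


def hotspot_track(fit: SubFit, mesh: BarrierMesh, domain: DomainSpec,
                  years=None, zero_bycatch_years=()) -> pd.DataFrame:
    """Per-year hotspot table (year, lon, lat, value, missing)."""
    term = _field_term(fit)
    if years is None:
        years = term.years if term.replicated else []
    rows = []
    for y in years:
        hs = annual_hotspot(fit, mesh, domain, y,
                            zero_bycatch_years=zero_bycatch_years)
        if hs is None:
            rows.append({"year": int(y), "lon": np.nan, "lat": np.nan,
                         "value": np.nan, "missing": True})
        else:
            rows.append({"year": int(y), "lon": hs[0], "lat": hs[1],
                         "value": hs[2], "missing": False})
    return pd.DataFrame(rows)


def zero_bycatch_years(records: pd.DataFrame) -> list:
    """Years present in the records with no positive-bycatch set."""
    tot = records.groupby("year")["bycatch"].sum()
    return [int(y) for y, v in tot.items() if v == 0]


def ccf_lagged(track: pd.DataFrame, index: ClimateSeries,
               max_lag: int = 5, min_overlap: int = 8) -> pd.DataFrame:
    """Cross-correlation of hotspot latitude with a lagged climate index.

    For lag k the pairs are (latitude(t), index(t-k)) over years where both
    exist (missing hotspot years dropped pairwise).  A lag with fewer than
    ``min_overlap`` pairs or zero variance on either side is flagged
    not-computable.  Significance is the two-sided 5% band |r| > 1.96/√n.
    """
    lat_by_year = {int(r.year): r.lat for r in track.itertuples()
                   if not r.missing and np.isfinite(r.lat)}
    idx_by_year = dict(zip(index.years.astype(int), index.values))
    rows = []
    for k in range(max_lag + 1):
        pairs = [(lat_by_year[t], idx_by_year[t - k])
                 for t in lat_by_year if (t - k) in idx_by_year]
        n = len(pairs)
        r = np.nan
        computable = n >= min_overlap
        if computable:
            a = np.array([p[0] for p in pairs])
            b = np.array([p[1] for p in pairs])
            if a.std() == 0 or b.std() == 0:
                computable = False
            else:
                r = float(np.corrcoef(a, b)[0, 1])
        sig = bool(computable and abs(r) > 1.96 / np.sqrt(n))
        rows.append({"lag": k, "r": r, "n": n, "significant": sig,
                     "computable": computable})
    return pd.DataFrame(rows)
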