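"""Domain types and I/O for the geostatistical child-survival analysis.

The analysis consumes four plain-text inputs emulating a DHS-style survey:

* ``children.csv`` — one row per under-five child: survival or censoring time
  in months, event indicator (1 = died before 60 months), cluster membership
  and categorical covariates;
* ``clusters.csv`` — georeferenced survey clusters (lon/lat degrees) with the
  administrative region each belongs to;
* ``coverage.csv`` — region-level intervention coverage (proportions, or
  percentages which are rescaled on input);
* ``adjacency.txt`` — the region adjacency graph as an undirected edge list.

This module also provides the two geometric primitives everything downstream
relies on: the great-circle distance matrix between clusters and the proper-CAR
building blocks (proximity matrix ``C``, diagonal ``D`` and the admissible
interval for the spatial-dependence parameter γ) derived from the adjacency
graph.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: The sixteen region-level intervention-coverage indicators.
INTERVENTIONS = (
    "itn_use",
    "malaria_treatment",
    "exclusive_breastfeeding",
    "breastfeeding_24h",
    "postnatal_check_24h",
    "measles_immunization",
    "dpt3_immunization",
    "all_antigen_immunization",
    "vitamin_a",
    "skilled_birth_attendance",
    "antenatal_visits",
    "family_planning",
    "iptp",
    "improved_sanitation",
    "improved_water",
    "itn_ownership",
)

REQUIRED_CHILD_COLUMNS = ("child_id", "cluster_id", "time_months", "event")

MAX_AGE_MONTHS = 60.0


class SchemaError(ValueError):
    """A required column is missing or a file is structurally malformed."""


class ValidationError(ValueError):
    """Row-level content violates a domain invariant."""


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between two points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_matrix(lonlat: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance matrix (km) for points in degrees.

    Parameters
    ----------
    lonlat : array of shape (m, 2)
        Longitude and latitude per location, in degrees.

    Returns
    -------
    (m, m) symmetric matrix with zero diagonal.
    """
    lonlat = np.asarray(lonlat, dtype=float)
    if lonlat.ndim != 2 or lonlat.shape[1] != 2:
        raise ValidationError("lonlat must have shape (m, 2)")
    lon, lat = lonlat[:, 0], lonlat[:, 1]
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValidationError("coordinates out of range: need lat in [-90, 90], lon in [-180, 180]")
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# spatial frame
# ---------------------------------------------------------------------------

@dataclass
class SpatialFrame:
    """Cluster geography: ids, coordinates, cluster→region map, distances (km)."""

    cluster_ids: np.ndarray
    lonlat: np.ndarray
    region_of: pd.Series  # index: cluster_id, value: region_id
    distances: np.ndarray = field(default=None)

    def __post_init__(self):
        self.cluster_ids = np.asarray(self.cluster_ids)
        self.lonlat = np.asarray(self.lonlat, dtype=float)
        if self.distances is None:
            self.distances = haversine_matrix(self.lonlat)
        missing = set(self.cluster_ids) - set(self.region_of.index)
        if missing:
            raise ValidationError(f"clusters without region assignment: {sorted(missing)[:5]}")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def region_index(self, region_ids) -> np.ndarray:
        """Index of each cluster's region within ``region_ids``."""
        lookup = {r: i for i, r in enumerate(region_ids)}
        return np.array([lookup[self.region_of.loc[c]] for c in self.cluster_ids])


def read_clusters(path) -> SpatialFrame:
    df = pd.read_csv(path)
    for col in ("cluster_id", "lon", "lat", "region_id"):
        if col not in df.columns:
            raise SchemaError(f"clusters file missing column {col!r}")
    return SpatialFrame(
        cluster_ids=df["cluster_id"].to_numpy(),
        lonlat=df[["lon", "lat"]].to_numpy(),
        region_of=df.set_index("cluster_id")["region_id"],
    )


# ---------------------------------------------------------------------------
# children
# ---------------------------------------------------------------------------

def validate_children(df: pd.DataFrame, spatial_frame: SpatialFrame | None = None) -> pd.DataFrame:
    """Check child records against the domain invariants.

    Raises :class:`ValidationError` naming the first offending rows. A child
    contributes a positive time at most 60 months and a binary event
    indicator; with a spatial frame given, its cluster must resolve there.
    """
    for col in REQUIRED_CHILD_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"children file missing column {col!r}")
    t = pd.to_numeric(df["time_months"], errors="coerce")
    e = pd.to_numeric(df["event"], errors="coerce")

    def offend(mask, what):
        if mask.any():
            rows = df.index[mask].tolist()[:5]
            raise ValidationError(f"{what} in rows {rows}")

    offend(t.isna(), "non-numeric time_months")
    offend(t <= 0, "time_months <= 0")
    offend(t > MAX_AGE_MONTHS, f"time_months > {MAX_AGE_MONTHS:g}")
    offend(~e.isin([0, 1]), "event not in {0, 1}")
    if spatial_frame is not None:
        known = set(spatial_frame.cluster_ids)
        offend(~df["cluster_id"].isin(known), "cluster_id not in spatial frame")
    out = df.copy()
    out["time_months"] = t.astype(float)
    out["event"] = e.astype(int)
    return out


def read_children(path, spatial_frame: SpatialFrame | None = None) -> pd.DataFrame:
    """Read and validate a child-record table."""
    return validate_children(pd.read_csv(path), spatial_frame)


def write_children(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# region graph
# ---------------------------------------------------------------------------

@dataclass
class RegionGraph:
    """Adjacency structure of the Q administrative regions.

    Holds the binary adjacency ω, neighbour counts g, row-normalised proximity
    matrix C (C_kl = ω_kl / g_k), diagonal D (D_kk = 1/g_k) and the open
    interval of γ values for which the proper-CAR covariance (I − γC)⁻¹D is
    positive definite, namely (1/λ_min, 1/λ_max) with λ the extreme
    eigenvalues of the symmetrised D^{-1/2} C D^{1/2}.
    """

    region_ids: list
    omega: np.ndarray

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=float)
        if omega.shape[0] != omega.shape[1]:
            raise ValidationError("adjacency matrix must be square")
        if not np.allclose(omega, omega.T) or np.any(np.diag(omega) != 0):
            raise ValidationError("adjacency must be symmetric with zero diagonal")
        self.omega = omega
        self.g = omega.sum(axis=1)
        if np.any(self.g < 1):
            isolated = [self.region_ids[i] for i in np.flatnonzero(self.g < 1)]
            raise ValidationError(f"isolated regions (no neighbours): {isolated}")
        self.C = omega / self.g[:, None]
        self.D = np.diag(1.0 / self.g)
        # eigenvalues of D^{-1/2} C D^{1/2} = omega_kl / sqrt(g_k g_l), symmetric
        sym = omega / np.sqrt(np.outer(self.g, self.g))
        self.car_eigenvalues = np.linalg.eigvalsh(sym)
        lam_min, lam_max = self.car_eigenvalues[0], self.car_eigenvalues[-1]
        self.gamma_bounds = (1.0 / lam_min, 1.0 / lam_max)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id) -> int:
        return self.region_ids.index(region_id)


def build_region_graph(edges, region_ids=None) -> RegionGraph:
    """Construct a :class:`RegionGraph` from an undirected edge list.

    ``edges`` is an iterable of (regionA, regionB) pairs or a path to a text
    file with one whitespace- or tab-separated pair per line (``#`` comments
    allowed). A disconnected graph triggers a warning; an isolated region is
    an error because its CAR diagonal entry 1/g_k would be undefined.
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "read"):
        edges = _read_edge_list(edges)
    edges = [tuple(e) for e in edges]
    nodes = sorted({n for e in edges for n in e}) if region_ids is None else list(region_ids)
    index = {n: i for i, n in enumerate(nodes)}
    unknown = [e for e in edges if e[0] not in index or e[1] not in index]
    if unknown:
        raise ValidationError(f"edges referencing unknown regions: {unknown[:5]}")
    omega = np.zeros((len(nodes), len(nodes)))
    for a, b in edges:
        if a == b:
            raise ValidationError(f"self-loop on region {a!r}")
        omega[index[a], index[b]] = omega[index[b], index[a]] = 1.0
    graph = RegionGraph(region_ids=nodes, omega=omega)
    G = nx.from_numpy_array(omega)
    if not nx.is_connected(G):
        import warnings

        warnings.warn("region adjacency graph is disconnected", stacklevel=2)
    return graph


def _read_edge_list(path):
    edges = []
    fh = open(path) if isinstance(path, (str, bytes)) else path
    with fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise SchemaError(f"malformed adjacency line: {line!r}")
            edges.append((parts[0].strip(), parts[1].strip()))
    return edges


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def read_coverage(path, interventions=None) -> pd.DataFrame:
    """Read a region × intervention coverage table.

    Values may be proportions in [0, 1] or percentages in (1, 100]; columns
    on the percentage scale are divided by 100. Internally coverage is always
    a proportion. Unknown intervention columns raise a schema error.
    """
    df = pd.read_csv(path)
    if "region_id" not in df.columns:
        raise SchemaError("coverage file missing column 'region_id'")
    df = df.set_index("region_id")
    known = set(INTERVENTIONS) if interventions is None else set(interventions)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"unrecognised intervention columns: {unknown}")
    out = df.astype(float)
    for col in out.columns:
        if out[col].max() > 1.0:
            out[col] = out[col] / 100.0
    if (out.values < 0).any() or (out.values > 1).any():
        raise ValidationError("coverage values must lie in [0, 1] after rescaling")
    return out


# ---------------------------------------------------------------------------
# bundled reference fixtures
# ---------------------------------------------------------------------------

def _dataset_path(name: str):
    return importlib.resources.files("geosurv.datasets").joinpath(name)


def load_burkina_adjacency() -> RegionGraph:
    """The 13-region Burkina Faso adjacency graph shipped with the package."""
    with _dataset_path("burkina_adjacency.txt").open() as fh:
        return build_region_graph(fh)


def load_burkina_coverage() -> pd.DataFrame:
    """Region-level coverage of the 16 interventions (proportions)."""
    with _dataset_path("burkina_coverage.csv").open() as fh:
        return read_coverage(fh)


def load_published_hrr() -> pd.DataFrame:
    """Published national and regional HRR medians with 95% credible intervals.

    One row per (intervention, scope) where scope is 'National' or a region
    name; columns hrr, lower, upper plus the as-printed importance star.
    """
    with _dataset_path("published_hrr.csv").open() as fh:
        df = pd.read_csv(fh)
    df["starred"] = df["starred"].astype(bool)
    return df
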