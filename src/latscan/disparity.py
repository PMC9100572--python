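"""Permutation-calibrated latitudinal disparity test.

For one gene, accessions are grouped by putative allele and their assigned
latitudes compared: two alleles with a pooled-variance two-sample t statistic
(two-sided, via |t|), more than two with a one-way ANOVA F. Significance is
calibrated empirically: latitudes are randomly permuted against the fixed
allele labels (1,000 permutations by default), the statistic recomputed each
time, and the 95th percentile of the permutation distribution used as the
critical value. An add-one empirical p-value is reported alongside:

    p = (1 + #{permuted statistic >= observed}) / (n_perm + 1)

For multi-allele genes, compact significance letters come from Fisher's least
significant difference on the ANOVA mean square error.

The module is organised statsmodels-style: :class:`GeneDisparity` is the model
for one gene (latitudes + allele labels), ``fit()`` returns a
:class:`GeneDisparityResults`; :class:`DisparityScan` runs the test over every
testable gene of an allele catalog and returns a :class:`ScanResults` with a
tidy results frame.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alleles import GeneAlleleCatalog, filter_testable_genes

__all__ = [
    "observed_statistic",
    "permutation_calibrate",
    "lsd_letters",
    "GeneDisparity",
    "GeneDisparityResults",
    "DisparityScan",
    "ScanResults",
    "scan_genes",
]


def _group_design(labels) -> tuple[np.ndarray, list, np.ndarray]:
    """Indicator matrix (n x k), group names, group sizes; groups in first-seen order."""
    labels = np.asarray(labels)
    names = list(dict.fromkeys(labels))
    G = np.column_stack([(labels == g).astype(float) for g in names])
    return G, names, G.sum(axis=0)


def _batch_statistic(V: np.ndarray, G: np.ndarray, ns: np.ndarray) -> np.ndarray:
    """|t| (k=2) or F (k>2) for each row of V, groups fixed by G.

    V is (P, n): P candidate latitude vectors over the same n accessions.
    Permuting a row leaves its grand mean and total sum of squares unchanged,
    which the F computation exploits.
    """
    k = G.shape[1]
    n = V.shape[1]
    S = V @ G                      # (P, k) group sums
    M = S / ns                     # group means
    if k == 2:
        SQ = (V**2) @ G
        var = (SQ - ns * M**2) / (ns - 1.0)
        sp2 = ((ns[0] - 1) * var[:, 0] + (ns[1] - 1) * var[:, 1]) / (n - 2.0)
        se = np.sqrt(sp2 * (1.0 / ns[0] + 1.0 / ns[1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (M[:, 0] - M[:, 1]) / se
        return np.abs(np.where(np.isfinite(t), t, 0.0))
    gm = V.mean(axis=1, keepdims=True)
    ssb = (ns * (M - gm) ** 2).sum(axis=1)
    sst = ((V - gm) ** 2).sum(axis=1)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n - k))
    return np.where(np.isfinite(F), F, 0.0)


def observed_statistic(latitudes, labels) -> tuple[str, float]:
    """Observed group-comparison statistic.

    Returns ``("t", |t|)`` for two groups (pooled-variance two-sample t, the
    absolute value for two-sided use) or ``("F", F)`` for more than two
    (one-way ANOVA).
    """
    y = np.asarray(latitudes, dtype=float)
    G, names, ns = _group_design(labels)
    if len(names) < 2:
        raise ValueError("need at least two allele groups")
    if (ns < 2).any():
        small = [g for g, n in zip(names, ns) if n < 2]
        raise ValueError(f"groups with fewer than two members: {small}")
    value = float(_batch_statistic(y[None, :], G, ns)[0])
    return ("t" if len(names) == 2 else "F"), value


def permutation_calibrate(
    latitudes,
    labels,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> tuple[float, float]:
    """Critical value and empirical p from random permutations.

    Latitudes are shuffled against the fixed labels ``n_perm`` times and the
    statistic (|t| or F) recomputed. The critical value is the empirical
    ``1 - alpha`` quantile (linear interpolation); the p-value uses the
    add-one rule, so it is never zero and never below ``1/(n_perm+1)``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable permutation tail")
    y = np.asarray(latitudes, dtype=float)
    G, _, ns = _group_design(labels)
    obs = _batch_statistic(y[None, :], G, ns)[0]
    rng = np.random.default_rng(seed)
    V = rng.permuted(np.broadcast_to(y, (n_perm, y.size)), axis=1)
    perm = _batch_statistic(V, G, ns)
    critical = float(np.percentile(perm, 100.0 * (1.0 - alpha)))
    p = float((1 + int((perm >= obs).sum())) / (n_perm + 1))
    return critical, p


def _lsd_significant(means, ns, mse, df, alpha) -> np.ndarray:
    """Boolean matrix: does pair (i, j) differ by Fisher's LSD?"""
    means = np.asarray(means, float)
    ns = np.asarray(ns, float)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    diff = np.abs(means[:, None] - means[None, :])
    lsd = tcrit * np.sqrt(mse * (1.0 / ns[:, None] + 1.0 / ns[None, :]))
    return diff > lsd


def lsd_letters(means, ns, mse: float, df: int, alpha: float = 0.05) -> list[str]:
    """Compact letter display from pairwise LSD comparisons.

    Letters are assigned by the insert-and-absorb procedure on groups sorted
    by descending mean; groups sharing any letter do not differ significantly.
    Returned in the order of the input groups.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    k = len(means)
    order = [int(g) for g in np.argsort(-np.asarray(means, float), kind="stable")]
    sig = _lsd_significant(means, ns, mse, df, alpha)

    # each set holds mutually non-different groups and maps to one letter
    letter_sets: list[set[int]] = [{order[0]}]
    for g in order[1:]:
        spawned: list[set[int]] = []
        for s in letter_sets:
            if not any(sig[g, h] for h in s):
                s.add(g)
            else:
                # duplicate the compatible part of s so non-different pairs
                # involving g still share a letter
                spawned.append({h for h in s if not sig[g, h]} | {g})
        letter_sets.extend(spawned)
        letter_sets = _absorb(letter_sets)
        if not any(g in s for s in letter_sets):
            letter_sets.append({g})

    # letters ordered by the highest-mean member of each set
    letter_sets.sort(key=lambda s: min(order.index(h) for h in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(k)]
    for li, s in enumerate(letter_sets):
        for g in s:
            out[g] += alphabet[li]
    return ["".join(sorted(x)) for x in out]


def _absorb(sets: list[set[int]]) -> list[set[int]]:
    """Drop letter sets contained in (or duplicating) another set."""
    keep: list[set[int]] = []
    for s in sorted(sets, key=len, reverse=True):
        if not any(s <= t for t in keep):
            keep.append(s)
    return keep


@dataclass
class GeneDisparityResults:
    """Fitted disparity test for one gene."""

    gene_id: str
    kind: str                    # "t" | "F"
    statistic: float
    critical_value: float
    pvalue: float
    alpha: float
    group_table: pd.DataFrame    # allele, n, mean_latitude
    deltas: pd.DataFrame         # antisymmetric pairwise mean differences, °N
    letters: dict[str, str] | None
    n_permutations: int
    seed: int | None
    df: tuple[int, int] | None = None   # (between, within) for F
    mse: float | None = None

    @property
    def significant(self) -> bool:
        return self.statistic >= self.critical_value

    def delta(self, a: str = "Alt1", b: str = "Ref") -> float:
        """Mean latitude of allele ``a`` minus that of allele ``b``, °N."""
        return float(self.deltas.loc[a, b])

    @property
    def northern_allele(self) -> str:
        """Allele whose carriers have the highest mean latitude."""
        tab = self.group_table.set_index("allele")["mean_latitude"]
        return str(tab.idxmax())

    def summary(self) -> str:
        lines = [
            f"Latitudinal disparity test: {self.gene_id}",
            f"  statistic ({self.kind}) = {self.statistic:.4f}"
            f"   permutation 95th pct = {self.critical_value:.4f}"
            f"   empirical p = {self.pvalue:.4g}"
            f"   {'significant' if self.significant else 'not significant'}"
            f" at alpha={self.alpha}",
            f"  permutations = {self.n_permutations}, seed = {self.seed}",
            "",
        ]
        tab = self.group_table.copy()
        if self.letters:
            tab["letter"] = tab["allele"].map(self.letters)
        lines.append(tab.to_string(index=False))
        return "\n".join(lines)


class GeneDisparity:
    """Disparity model for one gene: assigned latitudes grouped by allele.

    Parameters
    ----------
    latitudes : array-like of float, one per accession in the analysis stratum.
    labels : allele label per accession (same length/order as latitudes).
    gene_id : identifier carried into the results.
    """

    def __init__(self, latitudes, labels, gene_id: str = "gene"):
        self.latitudes = np.asarray(latitudes, dtype=float)
        self.labels = np.asarray(labels)
        if self.latitudes.shape != self.labels.shape:
            raise ValueError("latitudes and labels must align")
        self.gene_id = gene_id

    def fit(
        self, n_perm: int = 1000, alpha: float = 0.05, seed=None
    ) -> GeneDisparityResults:
        kind, obs = observed_statistic(self.latitudes, self.labels)
        critical, p = permutation_calibrate(
            self.latitudes, self.labels, n_perm=n_perm, alpha=alpha, seed=seed
        )
        G, names, ns = _group_design(self.labels)
        means = (self.latitudes @ G) / ns
        tab = pd.DataFrame(
            {"allele": names, "n": ns.astype(int), "mean_latitude": means}
        )
        deltas = pd.DataFrame(
            means[:, None] - means[None, :], index=names, columns=names
        )
        letters = None
        df = None
        mse = None
        if kind == "F":
            k, n = len(names), self.latitudes.size
            df = (k - 1, n - k)
            ssw = float(
                sum(
                    ((self.latitudes[self.labels == g] - m) ** 2).sum()
                    for g, m in zip(names, means)
                )
            )
            mse = ssw / df[1]
            lets = lsd_letters(means, ns, mse, df[1], alpha)
            letters = dict(zip(names, lets))
        seed_int = None if seed is None else int(seed) if np.isscalar(seed) else None
        return GeneDisparityResults(
            gene_id=self.gene_id,
            kind=kind,
            statistic=obs,
            critical_value=critical,
            pvalue=p,
            alpha=alpha,
            group_table=tab,
            deltas=deltas,
            letters=letters,
            n_permutations=n_perm,
            seed=seed_int,
            df=df,
            mse=mse,
        )


def gene_seed(master_seed: int, gene_id: str) -> np.random.SeedSequence:
    """Per-gene reproducible seed, independent of scan order or parallelism."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(gene_id.encode())])


@dataclass
class ScanResults:
    """Disparity results over all tested genes plus the skip ledger."""

    results: dict[str, GeneDisparityResults]
    skipped: dict[str, str]       # gene -> reason
    alpha: float

    def frame(self) -> pd.DataFrame:
        rows = []
        for gene, r in self.results.items():
            tab = r.group_table
            rows.append(
                {
                    "gene": gene,
                    "kind": r.kind,
                    "n_alleles": len(tab),
                    "n_total": int(tab["n"].sum()),
                    "alleles": ";".join(tab["allele"]),
                    "ns": ";".join(map(str, tab["n"])),
                    "means": ";".join(f"{m:.4f}" for m in tab["mean_latitude"]),
                    "delta_top": float(
                        tab["mean_latitude"].max() - tab["mean_latitude"].min()
                    ),
                    "statistic": r.statistic,
                    "critical": r.critical_value,
                    "p_empirical": r.pvalue,
                    "significant": r.significant,
                    "letters": ";".join(r.letters.values()) if r.letters else "",
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "gene", "kind", "n_alleles", "n_total", "alleles", "ns", "means",
                "delta_top", "statistic", "critical", "p_empirical", "significant",
                "letters",
            ],
        )
        if len(df):
            df = df.sort_values("p_empirical", kind="stable").reset_index(drop=True)
            # optional FDR column for users; the scan's own calls use raw p
            df["p_bh"] = _benjamini_hochberg(df["p_empirical"].to_numpy())
        return df

    @property
    def significant_genes(self) -> list[str]:
        return [g for g, r in self.results.items() if r.significant]

    def summary(self) -> str:
        df = self.frame()
        n_sig = int(df["significant"].sum()) if len(df) else 0
        head = (
            f"Latitudinal disparity scan: {len(self.results)} genes tested, "
            f"{len(self.skipped)} skipped, {n_sig} significant at alpha={self.alpha}"
        )
        return head + "\n" + df.to_string(index=False)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


class DisparityScan:
    """Run the disparity test over every testable gene of a panel stratum.

    Parameters
    ----------
    catalogs : per-gene allele catalogs (accession -> allele label).
    latitudes : Series of assigned latitudes indexed by accession id; only
        these accessions (the analysis stratum) enter the tests.
    candidate_genes : ordered gene list to test; defaults to all catalog genes.
    min_carriers : alleles carried by fewer accessions than this are dropped
        from a gene's comparison (their accessions omitted); also the
        testability threshold for the gene filter.
    """

    def __init__(
        self,
        catalogs: dict[str, GeneAlleleCatalog],
        latitudes: pd.Series,
        candidate_genes: list[str] | None = None,
        min_carriers: int = 10,
    ):
        self.catalogs = catalogs
        self.latitudes = latitudes
        self.candidate_genes = (
            list(candidate_genes) if candidate_genes is not None else list(catalogs)
        )
        self.min_carriers = min_carriers

    def fit(self, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0) -> ScanResults:
        testable = filter_testable_genes(
            self.catalogs, self.candidate_genes, self.min_carriers
        )
        results: dict[str, GeneDisparityResults] = {}
        skipped: dict[str, str] = {}
        accs = list(self.latitudes.index)
        for gene in testable:
            cat = self.catalogs[gene]
            labels = np.array([cat.assignments.get(a, "Ref") for a in accs])
            lats = self.latitudes.to_numpy(float)
            # drop rare alleles (stratum-level counts) from the comparison
            counts = pd.Series(labels).value_counts()
            keep_alleles = set(counts[counts >= self.min_carriers].index)
            mask = np.isin(labels, list(keep_alleles))
            y, lab = lats[mask], labels[mask]
            uniq = np.unique(lab)
            if len(uniq) < 2:
                skipped[gene] = "fewer than two alleles after rare-allele filter"
                continue
            if min(pd.Series(lab).value_counts()) < 2:
                skipped[gene] = "a group with fewer than two members"
                continue
            rng_seed = gene_seed(seed, gene)
            r = GeneDisparity(y, lab, gene_id=gene).fit(
                n_perm=n_perm, alpha=alpha, seed=rng_seed
            )
            r.seed = int(seed)
            results[gene] = r
        return ScanResults(results=results, skipped=skipped, alpha=alpha)


def scan_genes(
    catalogs,
    latitudes: pd.Series,
    candidate_genes=None,
    min_carriers: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ScanResults:
    """Functional wrapper around :class:`DisparityScan`."""
    return DisparityScan(catalogs, latitudes, candidate_genes, min_carriers).fit(
        n_perm=n_perm, alpha=alpha, seed=seed
    )
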