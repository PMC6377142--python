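"""All-pairs link fitting, validation, condition diffing and genome scans.

Every ordered gene pair (source as input, target as output; self-links
excluded) gets a first-order model per condition, fitted on the
replicate-averaged series.  Links whose fitness clears the threshold form
a condition network; diffing two networks yields the *common* links (whose
dynamics are then compared with the local nu-gap), the *lost* links
(regulation-loss network) and the *gained* links.  Per-gene connectivity
counts incoming plus outgoing links, so a reciprocal pair contributes two.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from dyde.data_model import AnalysisConfig, ExpressionDataset, average_replicates
from dyde.nugap import FrequencyBand, NuGapResult, nu_gap
from dyde.sysid import FirstOrderModel, fit_first_order

logger = logging.getLogger(__name__)

__all__ = [
    "Link",
    "GeneNetwork",
    "NetworkComparison",
    "pair_seed",
    "fit_all_pairs",
    "validate_links",
    "compare_networks",
    "rank_nu_gaps",
    "threshold_sweep",
    "connectivity_loss_sensitivity",
    "genome_scan_perturbed",
    "genome_scan_hubs",
    "write_sif",
    "network_to_json",
    "network_from_json",
]


@dataclass(frozen=True)
class Link:
    """A directed, fitted regulatory link (source regulates target)."""

    source: str
    target: str
    condition: str
    model: FirstOrderModel

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-regulation is excluded")

    @property
    def sign(self) -> str:
        return "activation" if self.model.a > 0 else "inhibition"

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class GeneNetwork:
    """Validated links over a gene universe at one fitness threshold."""

    genes: frozenset[str]
    links: dict[tuple[str, str], Link]
    threshold_pct: float

    def __post_init__(self) -> None:
        for key, link in self.links.items():
            if key != link.key:
                raise ValueError("links must be keyed by (source, target)")
            if link.model.fitness_pct is None or link.model.fitness_pct < self.threshold_pct:
                raise ValueError(f"link {key} below threshold {self.threshold_pct}")

    @property
    def n_links(self) -> int:
        return len(self.links)

    def degree(self, gene: str) -> int:
        """Incoming plus outgoing links of one gene."""
        return sum(1 for s, t in self.links if s == gene or t == gene)

    def incident(self, gene: str) -> set[tuple[str, str]]:
        return {k for k in self.links if gene in k}


@dataclass(frozen=True)
class NetworkComparison:
    """Diff of two condition networks sharing a gene universe."""

    common: list[tuple[Link, Link, NuGapResult]]
    lost: list[Link]
    gained: list[Link]
    connectivity: pd.DataFrame  # gene, degree_a, degree_b
    connectivity_loss_pct: dict[str, float]


def pair_seed(source: str, target: str, condition: str, rng_seed: int) -> int:
    """Stable per-pair RNG seed (crc32 of the identifying tuple)."""
    return zlib.crc32(f"{source}|{target}|{condition}|{rng_seed}".encode())


def fit_all_pairs(ds: ExpressionDataset, genes: Sequence[str] | None = None,
                  cfg: AnalysisConfig | None = None) -> list[Link]:
    """Fit the n^2 - n directed first-order models among the given genes."""
    cfg = cfg or AnalysisConfig()
    genes = list(genes) if genes is not None else list(ds.gene_ids)
    if len(genes) < 2:
        raise ValueError("need >=2 genes")
    series = {g: average_replicates(ds, g) for g in genes}
    links: list[Link] = []
    n_total = len(genes) * (len(genes) - 1)
    done = 0
    for src in genes:
        for tgt in genes:
            if src == tgt:
                continue
            done += 1
            try:
                model = fit_first_order(series[src], series[tgt], ds.times, cfg,
                                        seed=pair_seed(src, tgt, ds.condition, cfg.rng_seed))
                links.append(Link(source=src, target=tgt, condition=ds.condition, model=model))
            except Exception as exc:  # noqa: BLE001 - record and skip the pair
                logger.warning("pair %s->%s failed: %s", src, tgt, exc)
            if done % 50 == 0 or done == n_total:
                logger.info("fitted %d/%d pairs (%s)", done, n_total, ds.condition)
    return links


def validate_links(links: Iterable[Link], threshold_pct: float,
                   genes: Iterable[str] | None = None) -> GeneNetwork:
    """Keep links with fitness >= threshold; sign annotation comes from a."""
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    links = list(links)
    kept = {l.key: l for l in links
            if l.model.fitness_pct is not None and l.model.fitness_pct >= threshold_pct}
    universe = set(genes) if genes is not None else {g for l in links for g in l.key}
    return GeneNetwork(genes=frozenset(universe), links=kept, threshold_pct=threshold_pct)


def compare_networks(net_a: GeneNetwork, net_b: GeneNetwork,
                     band: FrequencyBand | str | None = None,
                     cfg: AnalysisConfig | None = None,
                     compute_gaps: bool = True) -> NetworkComparison:
    """Partition net_a/net_b links and nu-gap every common link.

    Per-gene connectivity loss is the fraction (%) of the gene's incident
    links in A that are absent from B.  ``compute_gaps=False`` skips the
    nu-gap evaluation (gap entries are None) for topology-only diffs.
    """
    cfg = cfg or AnalysisConfig()
    if net_a.genes != net_b.genes:
        raise ValueError("networks must share a gene universe")
    common_keys = sorted(set(net_a.links) & set(net_b.links))
    lost_keys = sorted(set(net_a.links) - set(net_b.links))
    gained_keys = sorted(set(net_b.links) - set(net_a.links))
    common = [(net_a.links[k], net_b.links[k],
               nu_gap(net_a.links[k].model, net_b.links[k].model, band=band, cfg=cfg)
               if compute_gaps else None)
              for k in common_keys]
    lost = [net_a.links[k] for k in lost_keys]
    gained = [net_b.links[k] for k in gained_keys]

    genes = sorted(net_a.genes)
    connectivity = pd.DataFrame({
        "gene": genes,
        "degree_a": [net_a.degree(g) for g in genes],
        "degree_b": [net_b.degree(g) for g in genes],
    })
    loss: dict[str, float] = {}
    for g in genes:
        incident_a = net_a.incident(g)
        if not incident_a:
            loss[g] = 0.0
        else:
            n_lost = sum(1 for k in incident_a if k not in net_b.links)
            loss[g] = 100.0 * n_lost / len(incident_a)
    return NetworkComparison(common=common, lost=lost, gained=gained,
                             connectivity=connectivity, connectivity_loss_pct=loss)


def rank_nu_gaps(cmp: NetworkComparison, k: int) -> list[tuple[Link, Link, NuGapResult]]:
    """Top-k common links by nu-gap, ties broken by (source, target)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(cmp.common, key=lambda item: (-item[2].value, item[0].source, item[0].target))
    return ranked[:k]


def threshold_sweep(links_a: Iterable[Link], reference: Iterable[tuple[str, str]],
                    thresholds: Sequence[float]) -> pd.DataFrame:
    """Coverage / false-positive table over a range of fitness thresholds.

    Coverage is validated-true-links / total-reference-links * 100; false
    positives are validated links absent from the reference edge list.
    """
    ref = {tuple(e) for e in reference}
    if not ref:
        raise ValueError("reference edge list is empty")
    links_a = list(links_a)
    rows = []
    for t in thresholds:
        validated = {l.key for l in links_a
                     if l.model.fitness_pct is not None and l.model.fitness_pct >= t}
        tp = len(validated & ref)
        fp = len(validated - ref)
        rows.append({"threshold": t, "coverage_pct": 100.0 * tp / len(ref),
                     "true_positives": tp, "false_positives": fp})
    return pd.DataFrame(rows)


def connectivity_loss_sensitivity(links_a: Iterable[Link], links_b: Iterable[Link],
                                  threshold: float, delta_pct: float = 5.0) -> pd.DataFrame:
    """Mean and sd of per-gene connectivity loss at thresholds {t-d, t, t+d}."""
    if delta_pct >= threshold:
        raise ValueError("delta must be smaller than the threshold")
    links_a = list(links_a)
    links_b = list(links_b)
    genes = sorted({g for l in links_a + links_b for g in l.key})
    samples: dict[str, list[float]] = {g: [] for g in genes}
    for t in (threshold - delta_pct, threshold, threshold + delta_pct):
        net_a = validate_links(links_a, t, genes=genes)
        net_b = validate_links(links_b, t, genes=genes)
        cmp = compare_networks(net_a, net_b, compute_gaps=False)
        for g in genes:
            samples[g].append(cmp.connectivity_loss_pct[g])
    return pd.DataFrame({
        "gene": genes,
        "loss_mean_pct": [float(np.mean(samples[g])) for g in genes],
        "loss_sd_pct": [float(np.std(samples[g], ddof=0)) for g in genes],
    })


def genome_scan_perturbed(ds_a: ExpressionDataset, ds_b: ExpressionDataset,
                          rhythmic_genes: Sequence[str],
                          cfg: AnalysisConfig | None = None) -> tuple[list, list]:
    """Scan for perturbed links among genes rhythmic in both conditions.

    Fits all directed pairs in both conditions, keeps pairs whose fitness
    clears the strict threshold in BOTH, nu-gaps them, and returns
    ``(candidates over the nu-gap threshold, all high-fitness pairs)``.
    Each entry is ``(link_a, link_b, NuGapResult)``.
    """
    cfg = cfg or AnalysisConfig()
    links_a = {l.key: l for l in fit_all_pairs(ds_a, rhythmic_genes, cfg)}
    links_b = {l.key: l for l in fit_all_pairs(ds_b, rhythmic_genes, cfg)}
    t = cfg.strict_fit_threshold_pct
    high = []
    for key in sorted(set(links_a) & set(links_b)):
        la, lb = links_a[key], links_b[key]
        if la.model.fitness_pct >= t and lb.model.fitness_pct >= t:
            gap = nu_gap(la.model, lb.model, cfg=cfg)
            high.append((la, lb, gap))
    candidates = [(la, lb, gap) for la, lb, gap in high if gap.value > cfg.nugap_threshold]
    return candidates, high


def genome_scan_hubs(ds_a: ExpressionDataset, ds_b: ExpressionDataset,
                     clock_genes: Sequence[str],
                     cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Rank non-clock genes by consistent, well-fitted links to the clock.

    Both directions (gene -> clock and clock -> gene) are fitted in both
    conditions; a link survives if its fitness clears the hub threshold in
    both conditions AND its nu-gap stays at or below the consistency cut.
    Returns a descending ranking by surviving-link count, ties by gene id.
    """
    cfg = cfg or AnalysisConfig()
    clock = list(clock_genes)
    for g in clock:
        ds_a.gene_index(g)
        ds_b.gene_index(g)
    others = [g for g in ds_a.gene_ids if g not in clock and g in ds_b.gene_ids]
    counts: dict[str, int] = {}
    links_out: dict[str, list[tuple[str, str]]] = {}
    times = ds_a.times
    from dyde.sysid import fit_first_order as _fit  # local alias

    def _series(ds, g):
        return average_replicates(ds, g)

    for gene in others:
        surviving = []
        for clk in clock:
            for src, tgt in ((gene, clk), (clk, gene)):
                try:
                    ma = _fit(_series(ds_a, src), _series(ds_a, tgt), times, cfg,
                              seed=pair_seed(src, tgt, ds_a.condition, cfg.rng_seed))
                    mb = _fit(_series(ds_b, src), _series(ds_b, tgt), ds_b.times, cfg,
                              seed=pair_seed(src, tgt, ds_b.condition, cfg.rng_seed))
                except Exception as exc:  # noqa: BLE001
                    logger.warning("hub pair %s->%s failed: %s", src, tgt, exc)
                    continue
                if (ma.fitness_pct >= cfg.hub_fit_threshold_pct
                        and mb.fitness_pct >= cfg.hub_fit_threshold_pct
                        and nu_gap(ma, mb, cfg=cfg).value <= cfg.nugap_threshold):
                    surviving.append((src, tgt))
        if surviving:
            counts[gene] = len(surviving)
            links_out[gene] = surviving
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    return pd.DataFrame({
        "gene": ranked,
        "clock_connectivity": [counts[g] for g in ranked],
        "links": [links_out[g] for g in ranked],
    })


# ---------------------------------------------------------------------------
# Serialization


def write_sif(net: GeneNetwork, path: str | Path) -> None:
    """Write a network as SIF: source <tab> activates|inhibits <tab> target."""
    lines = []
    for (s, t), link in sorted(net.links.items()):
        rel = "activates" if link.sign == "activation" else "inhibits"
        lines.append(f"{s}\t{rel}\t{t}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def network_to_json(net: GeneNetwork, path: str | Path) -> None:
    payload = {
        "threshold_pct": net.threshold_pct,
        "genes": sorted(net.genes),
        "links": [l.model.to_dict(source=s, target=t) | {"condition": l.condition}
                  for (s, t), l in sorted(net.links.items())],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def network_from_json(path: str | Path) -> GeneNetwork:
    d = json.loads(Path(path).read_text())
    links = {}
    for rec in d["links"]:
        link = Link(source=rec["source"], target=rec["target"],
                    condition=rec.get("condition", ""),
                    model=FirstOrderModel.from_dict(rec))
        links[link.key] = link
    return GeneNetwork(genes=frozenset(d["genes"]), links=links,
                       threshold_pct=float(d["threshold_pct"]))
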