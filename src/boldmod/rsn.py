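"""Resting-state network identification by template matching.

ICA component maps (voxelwise z-scores; the decomposition itself is an
input, produced by any standard ICA tool) are matched against named RSN
template sets.  Continuous templates are compared by in-brain spatial
correlation; binary templates by overlap (relative to the template) and the
Jaccard index of the z > 2 binarisation.  Assignment requires the maximum
similarity to converge in both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

Z_BINARIZE = 2.0  # z-score binarisation threshold (p < 0.05 uncorrected)


@dataclass
class ComponentMap:
    """A voxelwise z-score map with an identifier."""

    id: str
    z: np.ndarray

    def binarized(self, threshold: float = Z_BINARIZE) -> np.ndarray:
        return np.asarray(self.z) > threshold


@dataclass
class TemplateSet:
    """Named template maps; continuous (z) or binary, on a common grid."""

    maps: dict  # name -> np.ndarray
    binary: bool = False

    def __post_init__(self) -> None:
        if len(set(self.maps)) != len(self.maps):
            raise ValueError("template names must be unique")

    def merge(self, names: list, new_name: str) -> "TemplateSet":
        """Combine templates voxelwise (e.g. ventral + dorsal DMN into one).

        Binary templates are OR-combined; continuous ones take the voxelwise
        maximum.  Returns a new set with the sources replaced.
        """
        missing = [n for n in names if n not in self.maps]
        if missing:
            raise KeyError(f"unknown templates: {missing}")
        stacked = np.stack([np.asarray(self.maps[n], dtype=float) for n in names])
        combined = stacked.max(axis=0)
        maps = {k: v for k, v in self.maps.items() if k not in names}
        maps[new_name] = combined
        return TemplateSet(maps=maps, binary=self.binary)


def similarity(
    component: ComponentMap,
    template: np.ndarray,
    brain_mask: np.ndarray,
    template_binary: bool = False,
) -> dict:
    """Spatial correlation, overlap |A∩T|/|T|, and Jaccard |A∩T|/|A∪T|.

    A is the component's z > 2 binarisation; correlation uses in-brain
    voxels only (background would inflate it).  Empty binarised sets leave
    the Jaccard undefined (NaN, logged).
    """
    brain_mask = np.asarray(brain_mask, bool)
    comp = np.asarray(component.z, float)
    tmpl = np.asarray(template, float)
    if comp.shape != tmpl.shape:
        raise ValueError("component and template grids differ")
    a = component.binarized() & brain_mask
    t_bin = (tmpl > (0.5 if template_binary else Z_BINARIZE)) & brain_mask
    inter = float((a & t_bin).sum())
    union = float((a | t_bin).sum())
    overlap = inter / t_bin.sum() if t_bin.sum() else float("nan")
    if union == 0:
        logger.info("similarity: empty binarised sets; Jaccard undefined")
        jaccard = float("nan")
    else:
        jaccard = inter / union
    cv, tv = comp[brain_mask], tmpl[brain_mask]
    if cv.std() == 0 or tv.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(cv, tv)[0, 1])
    return {"r": r, "overlap": overlap, "jaccard": jaccard}


def _similarity_matrix(components, templates: TemplateSet, brain_mask, driver: str | None = None):
    names = list(templates.maps)
    driver = driver or ("jaccard" if templates.binary else "r")
    sim = np.full((len(components), len(names)), -np.inf)
    for i, comp in enumerate(components):
        for j, name in enumerate(names):
            s = similarity(comp, templates.maps[name], brain_mask, templates.binary)[driver]
            if np.isfinite(s):
                sim[i, j] = s
    return sim, names


def converging_match(
    components: list,
    templates: TemplateSet,
    brain_mask: np.ndarray,
    driver: str | None = None,
) -> dict:
    """Mutual-best-match assignment of components to templates.

    A pair (component, template) is assigned iff the template is the
    component's best match AND the component is the template's best match.
    The similarity driver defaults to spatial correlation for continuous
    templates and Jaccard for binary ones.  Returns ``{'assigned': {name:
    component_id}, 'unmatched_components': [...], 'unmatched_templates':
    [...]}``.
    """
    sim, names = _similarity_matrix(components, templates, brain_mask, driver)
    assigned = {}
    for i, comp in enumerate(components):
        j = int(np.argmax(sim[i]))
        if not np.isfinite(sim[i, j]):
            continue
        if int(np.argmax(sim[:, j])) == i:
            assigned[names[j]] = comp.id
    return {
        "assigned": assigned,
        "unmatched_components": [c.id for c in components if c.id not in assigned.values()],
        "unmatched_templates": [n for n in names if n not in assigned],
    }


def cross_set_match(
    components: list,
    reference_maps: dict,
    brain_mask: np.ndarray,
) -> dict:
    """Match each previously defined RSN to the component maximising correlation.

    ``reference_maps`` is ``{rsn_name: z_map}`` (e.g. RSNs already identified
    in another cohort); the assignment is one-directional and reports the
    winning correlation per RSN.
    """
    brain_mask = np.asarray(brain_mask, bool)
    out = {}
    for name, ref in reference_maps.items():
        rv = np.asarray(ref, float)[brain_mask]
        best_id, best_r = None, -np.inf
        for comp in components:
            cv = np.asarray(comp.z, float)[brain_mask]
            if cv.std() == 0 or rv.std() == 0:
                continue
            r = float(np.corrcoef(cv, rv)[0, 1])
            if r > best_r:
                best_id, best_r = comp.id, r
        out[name] = {"component": best_id, "r": best_r}
    return out
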