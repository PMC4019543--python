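"""Bind CEL intensity data to a library file.

The original workflow retargeted CEL files at a custom library by editing
their text headers; here the pairing is explicit and side-effect-free: a
library plus an :class:`~orthoarray.io.IntensityMatrix` yields one PM
matrix (probes × samples) per probe set, by pure coordinate lookup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntensityMatrix
from .libbuild import LibraryFile

__all__ = ["ProbesetIntensities", "remap", "remap_long"]


@dataclass
class ProbesetIntensities:
    """PM intensities for one probe set: DataFrame probes × samples."""

    probeset_id: str
    pm: pd.DataFrame

    @property
    def probe_ids(self) -> list[str]:
        return list(self.pm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.pm.columns)


def remap(
    intensities: IntensityMatrix, library: LibraryFile
) -> list[ProbesetIntensities]:
    """Look up each library probe's PM intensity in every sample.

    Pure lookup: values are never transformed, probe order follows the
    library, sample order follows the intensity matrix.  A library
    coordinate outside the grid is a hard error naming the probe set,
    probe and grid.
    """
    rows, cols = intensities.dims
    out: list[ProbesetIntensities] = []
    for ps in library.probesets:
        data = np.empty((ps.n_probe_pairs, intensities.n_samples))
        for i, probe in enumerate(ps.retained_probes):
            if not (0 <= probe.x < cols and 0 <= probe.y < rows):
                raise ValueError(
                    f"probe set {ps.probeset_id}, probe {probe.probe_id}: "
                    f"coordinate ({probe.x},{probe.y}) outside {rows}x{cols} grid"
                )
            data[i, :] = intensities.values[:, probe.y, probe.x]
        out.append(
            ProbesetIntensities(
                probeset_id=ps.probeset_id,
                pm=pd.DataFrame(
                    data,
                    index=[p.probe_id for p in ps.retained_probes],
                    columns=intensities.sample_ids,
                ),
            )
        )
    return out


def remap_long(intensities: IntensityMatrix, library: LibraryFile) -> pd.DataFrame:
    """Long-format view of :func:`remap`: one row per (probe, sample)."""
    frames = []
    for ps in remap(intensities, library):
        long = ps.pm.reset_index(names="probe_id").melt(
            id_vars="probe_id", var_name="sample_id", value_name="intensity"
        )
        long.insert(0, "probeset_id", ps.probeset_id)
        frames.append(long)
    if not frames:
        return pd.DataFrame(columns=["probeset_id", "probe_id", "sample_id", "intensity"])
    return pd.concat(frames, ignore_index=True)
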