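"""End-to-end computation: ROI dataset in, per-implant angle report out.

For every case, the O/A/B landmarks of each referenced vertebra are turned
into an anatomical frame; every implant site present (insertion + exit
point) is expressed in the frame named by the site catalog (transarticular
implants project in the C1 frame) and its two reported projected angles are
computed.  When the four safety-margin points of a site are present, the
four safety angles, the two in-plane corridor widths and the implant
length are computed as well.
"""

from __future__ import annotations

import math

from . import geometry
from .frames import build_frame, to_anatomical
from .geometry import (ImplantAxis, SafetyMargins, load_site_catalog,
                       projected_angles, safety_angles)
from .roi_io import AngleReportRow, ROIDataset

__all__ = ["compute_angle_report"]


def compute_angle_report(dataset: ROIDataset, implant_radius: float = 0.75,
                         catalog=None) -> list[AngleReportRow]:
    """Compute ProjA/SafA/width/length rows for every implant site present.

    ``implant_radius`` is in millimetres (default 0.75, i.e. a 1.5 mm
    implant).  Sites whose label is not in the catalog default to the C2
    frame with the (sagittal, dorsal) projection pair.  Safety quantities
    are NaN when a site carries no safety points.
    """
    catalog = catalog if catalog is not None else load_site_catalog()
    rows = []
    for case in dataset.cases():
        frames = {}
        for site in dataset.implant_sites(case):
            desc = catalog.get(site)
            frame_ref = desc.frame if desc else "C2"
            if frame_ref not in frames:
                frames[frame_ref] = build_frame(dataset.landmarks(case, frame_ref))
            frame = frames[frame_ref]
            I, E = dataset.implant_points(case, site)
            v = to_anatomical(frame, I, E)
            pa = projected_angles(v, desc)
            pair = pa.reported_pair
            proj1 = pair[0]
            proj2 = pair[1] if len(pair) > 1 else math.nan
            if dataset.has_safety_points(case, site):
                s = dataset.safety_points(case, site)
                implant = ImplantAxis(insertion_I=I, exit_E=E, site_id=site,
                                      frame_ref=frame_ref)
                sa = safety_angles(implant, SafetyMargins(
                    S1=s[0], S2=s[1], S3=s[2], S4=s[3],
                    implant_radius_r=implant_radius))
                rows.append(AngleReportRow(
                    case_id=case, site_label=site, proj_a1=proj1, proj_a2=proj2,
                    saf_a1=sa.saf_a1, saf_a2=sa.saf_a2, saf_a3=sa.saf_a3,
                    saf_a4=sa.saf_a4, width_plane1=sa.width_plane1,
                    width_plane2=sa.width_plane2,
                    implant_length=sa.implant_length))
            else:
                length = geometry.ImplantAxis(insertion_I=I, exit_E=E).length
                rows.append(AngleReportRow(
                    case_id=case, site_label=site, proj_a1=proj1, proj_a2=proj2,
                    saf_a1=math.nan, saf_a2=math.nan, saf_a3=math.nan,
                    saf_a4=math.nan, width_plane1=math.nan,
                    width_plane2=math.nan, implant_length=length))
    return rows
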