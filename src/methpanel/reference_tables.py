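"""Published subsite summary counts used as calibration inputs and fixtures.

These are the printed contingency counts from the discovery (450k tissue) and
clinical (stool MSP) studies of the SDC2/TFPI2 panel.  They serve two roles:

* regression fixtures — running :func:`methpanel.marker_screen.subsite_rate_table`
  on per-sample calls reconstructed from these counts must reproduce the
  printed rate columns;
* calibration — the synthetic-cohort defaults shape their per-location
  methylation probabilities after these rates.

Counts are ``location -> (positive, negative)`` where *positive* means
complement-marker (TFPI2) methylation positive within anchor (SDC2) negative
samples.
"""

from __future__ import annotations

from .data_model import Group, Location, SampleRecord

__all__ = [
    "TISSUE_COMPLEMENT_COUNTS",
    "STOOL_COMPLEMENT_COUNTS",
    "STOOL_SUBSITE_SENSITIVITY",
    "counts_to_calls",
]

#: Discovery cohort: TFPI2 positivity among the 50 SDC2-hypomethylated CRC
#: tissue samples, by tumor location (overall 44/50 = 88.0%).
TISSUE_COMPLEMENT_COUNTS: dict[Location, tuple[int, int]] = {
    Location.splenic_flexure: (2, 0),
    Location.sigmoid_colon: (14, 1),
    Location.rectosigmoid_junction: (9, 2),
    Location.descending_colon: (3, 0),
    Location.rectum_NOS: (5, 0),
    Location.colon_NOS: (4, 1),
    Location.ascending_colon: (3, 2),
    Location.hepatic_flexure: (1, 0),
    Location.transverse_colon: (1, 0),
    Location.other: (1, 0),
    Location.unknown: (1, 0),
}

#: Stool cohort: TFPI2 methylation-positive rate (Ct ≤ 38) within SDC2
#: methylation-negative (Ct > 38) specimens, per diagnostic group/location.
STOOL_COMPLEMENT_COUNTS: dict[Group, dict[Location, tuple[int, int]]] = {
    Group.CRC: {
        Location.left_colon: (5, 3),
        Location.right_colon: (1, 3),
        Location.sigmoid_colon: (8, 5),
        Location.rectum: (7, 6),
    },
    Group.adenoma: {
        Location.left_colon: (5, 12),
        Location.right_colon: (1, 16),
        Location.sigmoid_colon: (8, 15),
        Location.rectum: (7, 19),
    },
    Group.normal: {
        Location.unknown: (6, 202),
    },
}

#: Stool per-location single (SDC2) and dual (SDC2/TFPI2) detection
#: sensitivities with per-site case counts; right-colon entries are
#: back-solved from the printed overall sensitivities and per-site n's.
STOOL_SUBSITE_SENSITIVITY: dict[Group, dict[Location, tuple[int, float, float]]] = {
    # location: (n, single, dual)
    Group.CRC: {
        Location.left_colon: (49, 0.837, 0.939),
        Location.right_colon: (56, 0.930, 0.948),
        Location.sigmoid_colon: (86, 0.849, 0.942),
        Location.rectum: (98, 0.867, 0.939),
    },
    Group.adenoma: {
        Location.left_colon: (33, 0.485, 0.666),
        Location.right_colon: (46, 0.630, 0.652),
        Location.sigmoid_colon: (51, 0.549, 0.706),
        Location.rectum: (60, 0.567, 0.683),
    },
}


def counts_to_calls(
    counts: dict[Location, tuple[int, int]],
    group: Group = Group.CRC,
    cohort: str = "fixture",
    prefix: str = "S",
) -> tuple[dict[str, bool], list[SampleRecord]]:
    """Expand per-location (positive, negative) counts into per-sample calls.

    Returns (calls, records) suitable for
    :func:`methpanel.marker_screen.subsite_rate_table`.
    """
    calls: dict[str, bool] = {}
    records: list[SampleRecord] = []
    i = 0
    for loc, (n_pos, n_neg) in counts.items():
        for call, n in ((True, n_pos), (False, n_neg)):
            for _ in range(n):
                sid = f"{prefix}{i:04d}"
                calls[sid] = call
                records.append(
                    SampleRecord(sample_id=sid, group=group, location=loc, cohort=cohort)
                )
                i += 1
    return calls, records
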