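"""Label a small single-sample segment profile.

Builds a toy profile in memory — a mostly copy-neutral genome with one
broad single-copy gain and two focal amplifications — calls it, and prints
the per-segment five-state labels together with the estimated per-sample
thresholds. The labels are relative copy-number states: "0" neutral,
"+1"/"-1" low-level gain/loss (broad, low amplitude), "+2"/"-2" high-level
amplification/deletion (focal, high amplitude).
"""

from labelseg import Segment, SegmentProfile, call_sample

CHROM_LEN = 100_000_000


def seg(chrom: str, logr: float, frac: float, start: int = 1) -> Segment:
    length = round(frac * CHROM_LEN)
    return Segment(chrom=chrom, start=start, end=start + length - 1,
                   logR=logr, norm_length=frac)


segments = (
    [seg(str(c), 0.0, 0.95) for c in range(1, 9)]        # neutral background
    + [seg("9", 0.34, 0.60)]                             # broad one-copy gain
    + [seg("10", 1.45, 0.03), seg("11", 1.52, 0.04)]     # focal amplifications
    + [seg("12", -0.38, 0.45)]                           # broad one-copy loss
)
profile = SegmentProfile("patient_01", segments)

result = call_sample(profile)

print(f"sample {profile.sample_id}: {len(profile)} segments")
t = result.thresholds
print(f"baseline logR      {t.baseline_V:+.3f}")
print(f"low-level calls at {t.T_low_del:+.3f} / {t.T_low_dup:+.3f}")
print(f"high-level calls at {t.T_high_del:+.3f} / {t.T_high_dup:+.3f}")
print()
for s, label in zip(result.profile.segments, result.labels):
    print(f"  chr{s.chrom:>2}  logR {s.logR:+.2f}  "
          f"({s.norm_length:4.0%} of chrom)  -> {label}")
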