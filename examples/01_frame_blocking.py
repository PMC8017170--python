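"""Frame blocking: unify the length of variable-duration ECG records.

Builds three synthetic 12-lead records of different durations and shows
how each maps onto the same (10, 2000, 12) tensor: short records overlap
their frames, a 40-s record tiles exactly, longer records leave gaps.
"""

from ecgfb import frame_block, generate_record

for duration in (10.0, 40.0, 55.0):
    rec = generate_record({"Normal"}, duration, seed=1)
    blk = frame_block(rec)
    print(f"{duration:4.0f} s record ({rec.n_samples} samples)"
          f" -> block {blk.shape},"
          f" frameshift F_s = {blk.nominal_shift:7.1f},"
          f" overlap f_o = {blk.overlap:7.1f}")

# F_s = (S_l - F_l) / (F_n - 1): positive overlap means consecutive frames
# share samples (no signal is discarded); overlap 0 is an exact tiling;
# negative overlap means frames sample the record with gaps in between.
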