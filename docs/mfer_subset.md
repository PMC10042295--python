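# MFER-subset binary format

`ecg2img.signal_io` reads and writes a small, self-contained subset of a
tag–length–value (TLV) waveform encoding in the spirit of MFER (Medical
waveform Format Encoding Rules). It exists so the binary-format code path
can be exercised and round-trip-tested without hospital exports; it is
**not** an implementation of the full MFER standard and makes no
compatibility claims.

## TLV framing

Every record in the file is:

| field  | size | encoding              |
|--------|------|-----------------------|
| tag    | 1 B  | unsigned byte         |
| length | 4 B  | uint32, little-endian |
| value  | length B | tag-specific      |

All multi-byte integers and floats are **little-endian** throughout.

## Tags

| tag  | name              | value encoding | notes |
|------|-------------------|----------------|-------|
| 0x40 | preamble          | ASCII `MFER-SUBSET/1.0` (15 B) | must be the first TLV |
| 0x04 | channel count     | uint16 | number of waveform blocks that must follow |
| 0x05 | data type         | uint8: 0 = int16, 1 = int32 | sample integer type |
| 0x0B | sampling interval | float64, seconds | sampling rate = 1/interval |
| 0x0C | amplitude resolution | float64, mV per LSB | converts integers to mV |
| 0x12 | patient id        | UTF-8 string | |
| 0x16 | outcome label     | uint8: 0 survivor, 1 non-survivor | optional |
| 0x09 | lead name         | UTF-8 string (e.g. `II`, `V3`) | immediately precedes its waveform block |
| 0x1E | waveform block    | packed samples in the declared data type | amplitudes = int × resolution |

Tags with the high bit set (0x80–0xFF) are reserved for private/optional
use and are skipped by the reader. Any other unrecognized tag aborts
parsing with an unsupported-format error; a value that runs past
end-of-file, or fewer waveform blocks than the declared channel count,
raises a truncation error.

## Writer defaults

The writer emits int32 samples at a fixed resolution of 1e-6 mV/LSB, so
any clinically plausible amplitude (up to ±2147 mV) round-trips within
±0.5e-6 mV, and is byte-deterministic (the same record always produces
the same file). int16 (data type 0) is accepted by both reader and
writer for compactness at correspondingly coarser resolution.

## Example

A record with one lead `II` of two samples 0.5 mV and −0.25 mV written at
resolution 0.25 mV/LSB serializes as (hex, annotated):

```
40 0F000000 "MFER-SUBSET/1.0"      preamble
04 02000000 0100                   1 channel   (uint16)
05 01000000 01                     data type int32
0B 08000000 <float64 0.002>        sampling interval (500 Hz)
0C 08000000 <float64 0.25>         resolution 0.25 mV/LSB
12 01000000 "A"                    patient id
09 02000000 "II"                   lead name
1E 08000000 02000000 FFFFFFFF      samples +2, -1  ->  0.5, -0.25 mV
```
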