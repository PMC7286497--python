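# Gear archetype calibration, version 1.
#
# Anchored values: handline minimum fishing event 600 s; the overall trip
# duration envelope [2.3, 76.2] h with the purse-seine minimum at 2.3 h and
# the surface-drifting-gillnet maximum at 76.2 h; fishing-state speed modes
# below the 7 km/h visual threshold and transit modes below the 50 km/h
# filter.  All other numbers (exact speed modes and spreads, turning
# concentrations, transition diagonals, event minima for the other gears)
# are calibration ASSUMPTIONS chosen to produce plausible bimodal tracks;
# they are not measured values and are never used as acceptance truth.
version: 1
reference_interval_s: 5
start_area: {lat: [-0.6, 0.5], lon: [8.6, 9.5]}
profiles:
  SCG:  # sardine circling gillnet — single-day trips
    fishing_speed_kmh: [3.0, 1.2]
    transit_speed_kmh: [13.0, 3.0]
    angle_mean: [0.0, 0.0]
    angle_concentration: [0.5, 15.0]
    a_stay: [0.996, 0.996]
    trip_duration_h: [3.0, 10.0]
    min_fishing_event_s: 900
  SG:   # surface drifting gillnet — multi-day soaks
    fishing_speed_kmh: [1.5, 0.7]
    transit_speed_kmh: [11.0, 2.5]
    angle_mean: [0.0, 0.0]
    angle_concentration: [0.4, 15.0]
    a_stay: [0.9995, 0.997]
    trip_duration_h: [12.0, 76.2]
    min_fishing_event_s: 7200
  MCG:  # mullet circling gillnet — single-day trips
    fishing_speed_kmh: [3.0, 1.2]
    transit_speed_kmh: [13.0, 3.0]
    angle_mean: [0.0, 0.0]
    angle_concentration: [0.5, 15.0]
    a_stay: [0.996, 0.996]
    trip_duration_h: [3.0, 10.0]
    min_fishing_event_s: 900
  PS:   # purse seine — shortest trips, sets of ~30 min
    fishing_speed_kmh: [4.0, 1.5]
    transit_speed_kmh: [16.0, 3.5]
    angle_mean: [0.0, 0.0]
    angle_concentration: [0.6, 18.0]
    a_stay: [0.997, 0.996]
    trip_duration_h: [2.3, 8.0]
    min_fishing_event_s: 1800
  HL:   # handline — events as short as 10 minutes
    fishing_speed_kmh: [2.0, 0.9]
    transit_speed_kmh: [15.0, 3.0]
    angle_mean: [0.0, 0.0]
    angle_concentration: [0.5, 15.0]
    a_stay: [0.997, 0.995]
    trip_duration_h: [8.0, 40.0]
    min_fishing_event_s: 600
  LL:   # longline — overnight soaks
    fishing_speed_kmh: [2.5, 1.0]
    transit_speed_kmh: [14.0, 3.0]
    angle_mean: [0.0, 0.0]
    angle_concentration: [0.5, 16.0]
    a_stay: [0.9986, 0.996]
    trip_duration_h: [10.0, 30.0]
    min_fishing_event_s: 3600
  BG:   # bottom gillnet — successive net sets through day and night
    fishing_speed_kmh: [2.5, 1.0]
    transit_speed_kmh: [12.0, 2.5]
    angle_mean: [0.0, 0.0]
    angle_concentration: [0.5, 14.0]
    a_stay: [0.997, 0.995]
    trip_duration_h: [10.0, 30.0]
    min_fishing_event_s: 1800
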