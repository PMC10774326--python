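{
 "type": "FeatureCollection",
 "note": "Synthetic demo regions: approximate, hand-drawn rectangles loosely inspired by published sea turtle regional management units. NOT authoritative boundaries; supply your own region polygons for real analyses.",
 "features": [
  {"type": "Feature", "properties": {"name": "Central East Pacific"}, "geometry": {"type": "Polygon", "coordinates": [[[-130.0, -25.0], [-75.0, -25.0], [-75.0, 8.0], [-130.0, 8.0], [-130.0, -25.0]]]}},
  {"type": "Feature", "properties": {"name": "North West Atlantic"}, "geometry": {"type": "Polygon", "coordinates": [[[-100.0, 8.05], [-55.0, 8.05], [-55.0, 40.0], [-100.0, 40.0], [-100.0, 8.05]]]}},
  {"type": "Feature", "properties": {"name": "South West Atlantic"}, "geometry": {"type": "Polygon", "coordinates": [[[-70.0, -40.0], [-30.0, -40.0], [-30.0, 8.0], [-70.0, 8.0], [-70.0, -40.0]]]}},
  {"type": "Feature", "properties": {"name": "Central East Atlantic"}, "geometry": {"type": "Polygon", "coordinates": [[[-29.95, -10.0], [15.0, -10.0], [15.0, 25.0], [-29.95, 25.0], [-29.95, -10.0]]]}},
  {"type": "Feature", "properties": {"name": "Mediterranean"}, "geometry": {"type": "Polygon", "coordinates": [[[-6.0, 30.0], [37.0, 30.0], [37.0, 46.0], [-6.0, 46.0], [-6.0, 30.0]]]}},
  {"type": "Feature", "properties": {"name": "North West Indian"}, "geometry": {"type": "Polygon", "coordinates": [[[32.0, 8.0], [78.0, 8.0], [78.0, 29.95], [32.0, 29.95], [32.0, 8.0]]]}},
  {"type": "Feature", "properties": {"name": "South West Indian"}, "geometry": {"type": "Polygon", "coordinates": [[[30.0, -30.0], [60.0, -30.0], [60.0, 7.95], [30.0, 7.95], [30.0, -30.0]]]}},
  {"type": "Feature", "properties": {"name": "North East Indian"}, "geometry": {"type": "Polygon", "coordinates": [[[78.05, -5.0], [105.0, -5.0], [105.0, 25.0], [78.05, 25.0], [78.05, -5.0]]]}}
 ]
}
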