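{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Pose keypoint sequence",
 "description": "Per-frame normalized landmark coordinates from a 33-landmark full-body pose tracker, with video metadata. x and y are fractions of the frame width and height (y increases downward); z is relative depth and optional; visibility is a confidence in [0,1].",
 "type": "object",
 "required": ["Timeline", "Width", "Height", "AverageFPS"],
 "properties": {
  "Timeline": {
   "type": "object",
   "description": "Keypoint data across all frames",
   "required": ["TotalNumberOfFrames", "Items"],
   "properties": {
    "TotalNumberOfFrames": {
     "type": "integer",
     "minimum": 0,
     "description": "Number of frames with valid keypoints"
    },
    "Items": {
     "type": "array",
     "description": "Per-frame keypoint coordinates",
     "items": {
      "type": "object",
      "required": ["Landmarks"],
      "properties": {
       "Index": {"type": "integer", "minimum": 0, "description": "0-based frame ordinal, strictly increasing"},
       "Landmarks": {
        "type": "array",
        "minItems": 33,
        "maxItems": 33,
        "items": {
         "type": "object",
         "required": ["x", "y", "visibility"],
         "properties": {
          "x": {"type": "number"},
          "y": {"type": "number"},
          "z": {"type": "number"},
          "visibility": {"type": "number", "minimum": 0, "maximum": 1}
         }
        }
       }
      }
     }
    }
   }
  },
  "Width": {"type": "integer", "exclusiveMinimum": 0, "description": "Frame width (in pixels)"},
  "Height": {"type": "integer", "exclusiveMinimum": 0, "description": "Frame height (in pixels)"},
  "AverageFPS": {"type": "number", "exclusiveMinimum": 0, "description": "Video frame rate (frames per second)"}
 }
}
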