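"""Synthetic structural schema for IEEE 2791-2020 BioCompute Objects.

This is a JSON Schema (draft-07 subset) authored for this package as a
structural rendering of the IEEE 2791-2020 object model — the top-level
object with its etag/spec_version and the provenance, usability,
description, execution, io, parametric, and error domains.  It is a
synthetic stand-in, not the published schema files, and is validated
with :mod:`provflow.jsonschema_lite`.
"""

IEEE2791_SCHEMA_SYNTHETIC = {
    "type": "object",
    "required": [
        "object_id",
        "spec_version",
        "etag",
        "provenance_domain",
        "usability_domain",
        "description_domain",
        "execution_domain",
        "io_domain",
    ],
    "properties": {
        "object_id": {"type": "string", "minLength": 1},
        "spec_version": {"type": "string", "pattern": "2791"},
        "etag": {"type": "string", "pattern": "^[0-9a-f]{64}$"},
        "provenance_domain": {
            "type": "object",
            "required": ["name", "version", "created", "modified", "contributors", "license"],
            "properties": {
                "name": {"type": "string", "minLength": 1},
                "version": {"type": "string"},
                "created": {"type": "string", "format": "date-time"},
                "modified": {"type": "string", "format": "date-time"},
                "license": {"type": "string"},
                "contributors": {
                    "type": "array",
                    "minItems": 1,
                    "items": {
                        "type": "object",
                        "required": ["name", "contribution"],
                        "properties": {
                            "name": {"type": "string"},
                            "contribution": {"type": "array", "items": {"type": "string"}},
                        },
                    },
                },
                "review": {"type": "array"},
            },
        },
        "usability_domain": {"type": "array", "items": {"type": "string"}},
        "description_domain": {
            "type": "object",
            "required": ["pipeline_steps"],
            "properties": {
                "keywords": {"type": "array", "items": {"type": "string"}},
                "pipeline_steps": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": ["step_number", "name", "description", "input_list", "output_list"],
                        "properties": {
                            "step_number": {"type": "integer", "minimum": 0},
                            "name": {"type": "string"},
                            "description": {"type": "string"},
                            "version": {"type": "string"},
                            "input_list": {
                                "type": "array",
                                "items": {
                                    "type": "object",
                                    "required": ["uri"],
                                    "properties": {"uri": {"type": "string"}},
                                },
                            },
                            "output_list": {
                                "type": "array",
                                "items": {
                                    "type": "object",
                                    "required": ["uri"],
                                    "properties": {"uri": {"type": "string"}},
                                },
                            },
                        },
                    },
                },
            },
        },
        "execution_domain": {
            "type": "object",
            "required": [
                "script",
                "script_driver",
                "software_prerequisites",
                "external_data_endpoints",
                "environment_variables",
            ],
            "properties": {
                "script": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": ["uri"],
                        "properties": {
                            "uri": {
                                "type": "object",
                                "required": ["uri"],
                                "properties": {"uri": {"type": "string"}},
                            }
                        },
                    },
                },
                "script_driver": {"type": "string"},
                "software_prerequisites": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": ["name", "version", "uri"],
                        "properties": {
                            "name": {"type": "string"},
                            "version": {"type": "string"},
                            "uri": {
                                "type": "object",
                                "required": ["uri"],
                                "properties": {"uri": {"type": "string"}},
                            },
                        },
                    },
                },
                "external_data_endpoints": {"type": "array"},
                "environment_variables": {"type": "object"},
            },
        },
        "io_domain": {
            "type": "object",
            "required": ["input_subdomain", "output_subdomain"],
            "properties": {
                "input_subdomain": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": ["uri"],
                        "properties": {
                            "uri": {
                                "type": "object",
                                "required": ["uri"],
                                "properties": {"uri": {"type": "string"}},
                            }
                        },
                    },
                },
                "output_subdomain": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": ["mediatype", "uri"],
                        "properties": {
                            "mediatype": {"type": "string"},
                            "uri": {
                                "type": "object",
                                "required": ["uri"],
                                "properties": {"uri": {"type": "string"}},
                            },
                        },
                    },
                },
            },
        },
        "parametric_domain": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["param", "value", "step"],
                "properties": {
                    "param": {"type": "string"},
                    "value": {"type": "string"},
                    "step": {"type": "string"},
                },
            },
        },
        "error_domain": {
            "type": "object",
            "properties": {
                "empirical_error": {"type": "object"},
                "algorithmic_error": {"type": "object"},
            },
        },
        "extension_domain": {"type": "array"},
    },
}
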