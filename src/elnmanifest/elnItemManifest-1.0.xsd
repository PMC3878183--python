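<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="urn:elnmanifest:schema:1.0"
           xmlns:eim="urn:elnmanifest:schema:1.0"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <!-- Knowledge-layer metadata record for one ELN unit. -->

  <xs:simpleType name="nonEmptyToken">
    <xs:restriction base="xs:token">
      <xs:minLength value="1"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="absoluteUri">
    <!-- scheme ":" remainder; relative references are not acceptable
         as open-access linked-data identifiers -->
    <xs:restriction base="xs:anyURI">
      <xs:pattern value="[A-Za-z][A-Za-z0-9+.\-]*:\S+"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="mediaType">
    <!-- IANA type/subtype -->
    <xs:restriction base="xs:token">
      <xs:pattern value="[A-Za-z0-9][A-Za-z0-9!#$&amp;^_.+\-]*/[A-Za-z0-9][A-Za-z0-9!#$&amp;^_.+\-]*"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="unitTypeValue">
    <xs:restriction base="xs:token">
      <xs:enumeration value="Package"/>
      <xs:enumeration value="Record"/>
      <xs:enumeration value="Component"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="contactMode">
    <xs:restriction base="xs:token">
      <xs:enumeration value="EMail"/>
      <xs:enumeration value="SystemURI"/>
      <xs:enumeration value="Instruction"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="contactType">
    <xs:simpleContent>
      <xs:extension base="eim:nonEmptyToken">
        <xs:attribute name="mode" type="eim:contactMode" use="required"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:element name="elnItemManifest">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Title" type="eim:nonEmptyToken"/>
        <xs:element name="Keywords" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Keyword" type="eim:nonEmptyToken"
                          minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="Identifiers">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="PrimaryLocalIdentifier" type="eim:nonEmptyToken"/>
              <xs:element name="OtherLocalIdentifier" type="eim:nonEmptyToken"
                          minOccurs="0" maxOccurs="unbounded"/>
              <xs:element name="AccessIdentifier" type="eim:absoluteUri" minOccurs="0"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="Contact" type="eim:contactType"/>
        <xs:element name="LicensingBasis" type="eim:nonEmptyToken" minOccurs="0"/>
        <xs:element name="Contributors">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="ContributorInformation" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Role" type="xs:token"/>
                    <xs:element name="Name" type="eim:nonEmptyToken"/>
                    <xs:element name="Identifier" type="eim:nonEmptyToken"
                                minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="Source" type="eim:nonEmptyToken"/>
        <xs:element name="Date">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="CreationDate" type="xs:date"/>
              <xs:element name="ReleaseDate" type="xs:date" minOccurs="0"/>
              <xs:element name="PublicationDate" type="xs:date" minOccurs="0"/>
              <xs:element name="SubmissionDate" type="xs:date" minOccurs="0"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="RelatedItems" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="RelatedItem" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Relationship" type="eim:nonEmptyToken"/>
                    <xs:element name="Id" type="eim:nonEmptyToken"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="Content">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="ContentItem" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Description" type="eim:nonEmptyToken"/>
                    <xs:element name="DataType" type="eim:mediaType"/>
                    <xs:element name="Locator" type="eim:absoluteUri" minOccurs="0"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <!-- extension point: foreign-namespace elements are tolerated on
             read and dropped on write -->
        <xs:any namespace="##other" processContents="lax"
                minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="unitType" type="eim:unitTypeValue" use="required"/>
      <xs:attribute name="schemaVersion" type="eim:nonEmptyToken" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
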